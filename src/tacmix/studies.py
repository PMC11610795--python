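"""Study harnesses: consistency/refinement simulations and LOOCV bands.

Two experiment designs are provided.

* The consistency study generates one growing synthetic panel and tracks the
  discrepancy D between the fitted mixing distribution and the truth as the
  number of drinking episodes m increases, plus refinement tables of the
  normalized discrepancies D_bar_M (grid refinement at fixed discretization)
  and D_bar_N (discretization refinement at fixed grid).

* The leave-one-out cross-validation study fits the mixing distribution on
  all episodes but one, draws parameter vectors from the fitted measure,
  simulates posterior-predictive TAC curves for the held-out BrAC input
  (observation noise included), and reports the pointwise mean curve, a 95%
  percentile band, and per-statistic intervals for peak TAC, peak time and
  AUC together with coverage of the measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import (
    Episode,
    NoiseModel,
    OperatorCache,
    build_log_density_matrix,
)
from .measures import (
    DiscreteMeasure,
    ParameterGrid,
    discrepancy_D,
    normalized_discrepancies,
)
from .npml import SolverConfig, fit_npml
from .params import ParamDomain
from .pde import impulse_response, simulate_output_convolution
from .synthetic import PopulationSpec, generate_population

__all__ = [
    "TacStats",
    "tac_statistics",
    "ConsistencyResult",
    "consistency_study",
    "refinement_studies",
    "LoocvEpisodeResult",
    "LoocvResult",
    "loocv_study",
]


@dataclass(frozen=True)
class TacStats:
    """Clinically relevant summaries of one TAC curve."""

    peak_value: float
    peak_time: float
    auc: float


def tac_statistics(times, y) -> TacStats:
    """Peak value, time of the (first) peak, and trapezoidal AUC of a curve."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if times.shape != y.shape or times.ndim != 1 or len(y) < 2:
        raise ValueError("need equal-length 1-D sequences with at least two samples")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    k = int(np.argmax(y))  # first index attaining the maximum
    return TacStats(
        peak_value=float(y[k]),
        peak_time=float(times[k]),
        auc=float(np.trapezoid(y, times)),
    )


@dataclass(frozen=True)
class ConsistencyResult:
    """Rows of (size, discrepancy) from a consistency or refinement ladder."""

    kind: str                      # "m", "M" or "N"
    rows: tuple                    # ((size, statistic), ...)
    seed: int
    config: dict = field(default_factory=dict)

    def sizes(self) -> list:
        return [r[0] for r in self.rows]

    def values(self) -> list:
        return [r[1] for r in self.rows]


def _fit_measure(L, cfg: SolverConfig | None) -> DiscreteMeasure:
    return fit_npml(L, cfg or SolverConfig()).measure


def consistency_study(spec: PopulationSpec, m_values, grid: ParameterGrid,
                      N: int, noise: NoiseModel, cfg: SolverConfig | None = None,
                      cache: OperatorCache | None = None) -> ConsistencyResult:
    """D versus the number of episodes m, on one nested growing panel.

    A single panel of max(m_values) episodes is generated; the fit for each m
    uses the first m episodes, so smaller datasets are prefixes of larger
    ones and the trend is within one growing dataset.
    """
    m_values = sorted(set(int(m) for m in m_values))
    if not m_values:
        raise ValueError("m_values must be nonempty")
    cache = cache or OperatorCache()
    full_spec = PopulationSpec(**{**spec.__dict__, "m": max(m_values)})
    episodes, _ = generate_population(full_spec, cache=cache)
    L = build_log_density_matrix(episodes, grid, N, noise, cache=cache)
    rows = []
    for m in m_values:
        measure = _fit_measure(L.subset(range(m)), cfg)
        rows.append((m, discrepancy_D(measure, spec.truth)))
    return ConsistencyResult(kind="m", rows=tuple(rows), seed=spec.seed,
                             config={"M": grid.M, "N": int(N), "sigma2": noise.sigma2})


def refinement_studies(spec: PopulationSpec, M_list, N_list,
                       fixed_grid: ParameterGrid, fixed_N: int,
                       noise: NoiseModel, domain: ParamDomain | None = None,
                       cfg: SolverConfig | None = None,
                       cache: OperatorCache | None = None):
    """Normalized-discrepancy refinement tables on one fixed panel.

    Returns ``(table_M, table_N)``: D_bar_M across grid sizes in ``M_list``
    (total node counts, perfect squares) at discretization ``fixed_N``, and
    D_bar_N across discretization levels in ``N_list`` on ``fixed_grid``.
    """
    if not M_list and not N_list:
        raise ValueError("at least one refinement ladder must be nonempty")
    cache = cache or OperatorCache()
    domain = domain or fixed_grid.domain
    episodes, _ = generate_population(spec, cache=cache)

    rows_M = []
    for M in M_list:
        m_axis = int(round(np.sqrt(M)))
        if m_axis * m_axis != int(M):
            raise ValueError(f"grid size {M} is not a perfect square")
        grid = ParameterGrid(domain, m_axis, m_axis)
        L = build_log_density_matrix(episodes, grid, fixed_N, noise, cache=cache)
        D = discrepancy_D(_fit_measure(L, cfg), spec.truth)
        rows_M.append((int(M), normalized_discrepancies(D, int(M), fixed_N)[0]))

    rows_N = []
    for N in N_list:
        L = build_log_density_matrix(episodes, fixed_grid, int(N), noise, cache=cache)
        D = discrepancy_D(_fit_measure(L, cfg), spec.truth)
        rows_N.append((int(N), normalized_discrepancies(D, fixed_grid.M, int(N))[1]))

    table_M = ConsistencyResult(kind="M", rows=tuple(rows_M), seed=spec.seed,
                                config={"fixed_N": int(fixed_N), "m": spec.m})
    table_N = ConsistencyResult(kind="N", rows=tuple(rows_N), seed=spec.seed,
                                config={"fixed_M": fixed_grid.M, "m": spec.m})
    return table_M, table_N


@dataclass(frozen=True)
class LoocvEpisodeResult:
    """Held-out prediction record for one episode."""

    episode_id: str
    times: np.ndarray
    measured: np.ndarray
    estimated: np.ndarray          # pointwise mean of the predictive draws
    lower: np.ndarray              # pointwise band percentiles
    upper: np.ndarray
    measured_stats: TacStats
    estimated_stats: TacStats
    stat_intervals: dict           # stat name -> (lo, hi)
    covered: dict                  # stat name -> bool
    degenerate: bool               # fitted measure collapsed to a single atom


@dataclass(frozen=True)
class LoocvResult:
    episodes: tuple
    n_draws: int
    band: tuple
    seed: int

    def coverage_count(self, stat: str = "peak_value") -> int:
        return sum(1 for e in self.episodes if e.covered[stat])


def loocv_study(episodes, grid: ParameterGrid, N: int, noise: NoiseModel,
                n_draws: int = 100, band: tuple = (2.5, 97.5), seed: int = 0,
                cfg: SolverConfig | None = None,
                cache: OperatorCache | None = None,
                predictive_sigma2: float | None = None) -> LoocvResult:
    """Leave-one-out predictive bands and statistic coverage.

    For each episode the mixing measure is refitted on the others, ``n_draws``
    parameter vectors are drawn from it, and posterior-predictive TAC curves
    (forward output plus N(0, predictive_sigma2) observation noise, default
    the fitting noise variance) are simulated from the held-out BrAC input.
    The band takes pointwise percentiles; each statistic's interval comes from
    the per-draw statistics, not the band curves.
    """
    episodes = list(episodes)
    if len(episodes) < 2:
        raise ValueError("LOOCV needs at least two episodes")
    if n_draws < 2:
        raise ValueError("need at least two predictive draws")
    cache = cache or OperatorCache()
    if predictive_sigma2 is None:
        predictive_sigma2 = noise.sigma2
    L = build_log_density_matrix(episodes, grid, N, noise, cache=cache)
    rng = np.random.default_rng(seed)

    records = []
    for e, ep in enumerate(episodes):
        train_rows = [i for i in range(len(episodes)) if i != e]
        measure = _fit_measure(L.subset(train_rows), cfg)
        idx = rng.choice(grid.M, size=n_draws, p=measure.weights)
        degenerate = len(np.unique(idx)) == 1

        curves = np.empty((n_draws, ep.n))
        for r, j in enumerate(idx):
            dsys = cache.get(grid.nodes[j], ep.tau, int(N))
            g = impulse_response(dsys, ep.n)
            curves[r] = simulate_output_convolution(g, ep.u)
        if predictive_sigma2 > 0:
            curves += rng.normal(0.0, np.sqrt(predictive_sigma2), size=curves.shape)

        mean_curve = curves.mean(axis=0)
        lower = np.percentile(curves, band[0], axis=0)
        upper = np.percentile(curves, band[1], axis=0)

        times = ep.times
        measured_stats = tac_statistics(times, ep.obs)
        estimated_stats = tac_statistics(times, mean_curve)
        draw_stats = [tac_statistics(times, c) for c in curves]
        intervals, covered = {}, {}
        for name in ("peak_value", "peak_time", "auc"):
            vals = np.array([getattr(s, name) for s in draw_stats])
            lo, hi = np.percentile(vals, band[0]), np.percentile(vals, band[1])
            intervals[name] = (float(lo), float(hi))
            covered[name] = bool(lo <= getattr(measured_stats, name) <= hi)

        records.append(LoocvEpisodeResult(
            episode_id=ep.id, times=times, measured=ep.obs.copy(),
            estimated=mean_curve, lower=lower, upper=upper,
            measured_stats=measured_stats, estimated_stats=estimated_stats,
            stat_intervals=intervals, covered=covered, degenerate=degenerate))
    return LoocvResult(episodes=tuple(records), n_draws=n_draws,
                       band=tuple(band), seed=seed)


def plot_loocv_band(record: LoocvEpisodeResult, path=None):
    """Measured/estimated TAC with the shaded predictive band (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.fill_between(record.times, record.lower, record.upper,
                    alpha=0.3, label="95% band")
    ax.plot(record.times, record.measured, lw=1.0, label="measured TAC")
    ax.plot(record.times, record.estimated, lw=1.5, ls="--", label="estimated TAC")
    ax.set_xlabel("time (dimensionless)")
    ax.set_ylabel("TAC")
    ax.set_title(f"episode {record.episode_id}")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
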