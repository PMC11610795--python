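"""Synthetic drinking-episode panels for simulation studies.

Lab BrAC recordings are not redistributable, so study inputs are emulated by
piecewise-linear single-peak BrAC profiles (rise to a peak, optional plateau,
linear decline, zero tail) with per-episode randomized shape.  Subject
parameters are drawn i.i.d. from a configurable truth law — the product
Beta(2, 5) used in the consistency study, or any discrete measure — and TAC
observations are the Galerkin forward output plus N(0, sigma^2) noise, so the
generator matches the statistical model the estimator assumes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .likelihood import Episode, OperatorCache
from .measures import DiscreteMeasure, ProductBeta
from .pde import impulse_response, simulate_output_convolution

__all__ = ["BracProfile", "PopulationSpec", "make_brac_input",
           "sample_true_params", "generate_population"]


@dataclass(frozen=True)
class BracProfile:
    """Piecewise-linear single-peak BrAC curve, in dimensionless time/level."""

    t_rise: float
    t_peak_hold: float
    t_fall: float
    peak: float
    horizon: float
    tau: float

    def __post_init__(self) -> None:
        if self.t_rise <= 0 or self.t_fall <= 0 or self.t_peak_hold < 0:
            raise ValueError("rise/fall must be positive, hold nonnegative")
        if self.peak <= 0 or self.tau <= 0:
            raise ValueError("peak and tau must be positive")
        if self.horizon < self.t_rise + self.t_peak_hold + self.t_fall:
            raise ValueError(
                f"horizon {self.horizon} is shorter than the profile "
                f"({self.t_rise}+{self.t_peak_hold}+{self.t_fall})")

    def value(self, t: float) -> float:
        if t <= 0:
            return 0.0
        if t < self.t_rise:
            return self.peak * t / self.t_rise
        t2 = self.t_rise + self.t_peak_hold
        if t <= t2:
            return self.peak
        t3 = t2 + self.t_fall
        if t < t3:
            return self.peak * (t3 - t) / self.t_fall
        return 0.0


@dataclass(frozen=True)
class PopulationSpec:
    """Study conditions for one synthetic panel.

    Defaults mirror the simulation-study setting: parameters i.i.d.
    Beta(2, 5) per coordinate, observation noise variance 1e-6, sampling
    interval 0.1 and a 12-unit horizon; episode-level BrAC shapes randomize
    within the configured ranges so episodes differ as lab episodes do.
    """

    m: int = 10
    truth: object = field(default_factory=ProductBeta)   # ProductBeta or DiscreteMeasure
    sigma2: float = 1e-6
    N_sim: int = 128
    tau: float = 0.1
    horizon: float = 12.0
    peak_range: tuple = (0.05, 0.12)
    t_rise_range: tuple = (0.5, 2.0)
    t_fall_range: tuple = (2.0, 6.0)
    t_hold_range: tuple = (0.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.N_sim < 1:
            raise ValueError("m and N_sim must be at least 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        longest = self.t_rise_range[1] + self.t_hold_range[1] + self.t_fall_range[1]
        if self.horizon < longest:
            raise ValueError(
                f"horizon {self.horizon} cannot accommodate the longest profile "
                f"({longest}) the randomization ranges allow")


def make_brac_input(profile: BracProfile) -> np.ndarray:
    """Sample the profile at the hold instants {0, tau, ..., (K-1) tau}.

    K = round(horizon / tau); u[k] is the BrAC held on [k tau, (k+1) tau).
    """
    K = int(round(profile.horizon / profile.tau))
    t = profile.tau * np.arange(K)
    return np.array([profile.value(tk) for tk in t])


def sample_true_params(spec: PopulationSpec, rng=None) -> np.ndarray:
    """m i.i.d. (q1, q2) draws from the truth law, as an (m, 2) array."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    truth = spec.truth
    if isinstance(truth, ProductBeta):
        return rng.beta(truth.alpha, truth.beta, size=(spec.m, 2))
    if isinstance(truth, DiscreteMeasure):
        idx = rng.choice(truth.grid.M, size=spec.m, p=truth.weights)
        return truth.grid.nodes[idx].copy()
    raise TypeError(f"unsupported truth sampler {type(truth).__name__}")


def _random_profile(spec: PopulationSpec, rng) -> BracProfile:
    return BracProfile(
        t_rise=rng.uniform(*spec.t_rise_range),
        t_peak_hold=rng.uniform(*spec.t_hold_range),
        t_fall=rng.uniform(*spec.t_fall_range),
        peak=rng.uniform(*spec.peak_range),
        horizon=spec.horizon,
        tau=spec.tau,
    )


def generate_population(spec: PopulationSpec,
                        cache: OperatorCache | None = None):
    """Generate the panel: per episode a randomized BrAC profile, a parameter
    draw, the simulated TAC and additive Gaussian noise.

    Returns ``(episodes, true_params)``; the true parameter array is kept for
    recovery tests and is written to a JSON sidecar by the CLI.
    """
    # Separate structure/noise streams so the noise-free panel at a given seed
    # is exactly the sigma2 > 0 panel minus its noise.
    struct_stream, noise_stream = np.random.SeedSequence(spec.seed).spawn(2)
    rng = np.random.default_rng(struct_stream)
    rng_noise = np.random.default_rng(noise_stream)
    cache = cache or OperatorCache()
    params = sample_true_params(spec, rng)
    episodes = []
    for i in range(spec.m):
        profile = _random_profile(spec, rng)
        u = make_brac_input(profile)
        dsys = cache.get(params[i], spec.tau, spec.N_sim)
        g = impulse_response(dsys, len(u))
        y = simulate_output_convolution(g, u)
        noise = rng_noise.normal(0.0, np.sqrt(spec.sigma2), size=len(u)) if spec.sigma2 > 0 else 0.0
        episodes.append(Episode(id=f"ep{i:03d}", tau=spec.tau, u=u, obs=y + noise))
    return episodes, params
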