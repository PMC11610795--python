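"""Mixed-effects observation model and mixture log-likelihood.

Each drinking episode i contributes observations

    Y_{k,i} = y_k(q_i) + e_{k,i},   k = 1..n_i,   e_{k,i} ~ N(0, sigma^2),

where y_k(q_i) is the sampled TAC output of the diffusion forward model for
that episode's BrAC input and subject-specific parameters q_i.  Under a
candidate mixing measure P = sum_j p_j delta_{q_j} the log-likelihood is

    sum_i log sum_j exp( log p_j + L[i, j] ),

with L[i, j] the per-episode Gaussian log-density at grid node q_j.  All
computation stays in the log domain; the inner sum uses log-sum-exp to avoid
the underflow that the raw product form suffers at small sigma^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .measures import ParameterGrid
from .params import as_param_vector
from .pde import (
    DiscreteTimeSystem,
    assemble_galerkin,
    impulse_response,
    simulate_output_convolution,
    time_discretize,
)

__all__ = [
    "Episode",
    "NoiseModel",
    "LogDensityMatrix",
    "OperatorCache",
    "subject_log_density",
    "build_log_density_matrix",
    "mixture_loglik",
    "DegenerateLikelihoodError",
]


class DegenerateLikelihoodError(ValueError):
    """Every admissible node has zero likelihood for some episode."""


@dataclass(frozen=True)
class Episode:
    """One drinking episode on a uniform tau-grid.

    ``u[k-1]`` (BrAC) is held on [(k-1) tau, k tau); ``obs[k-1]`` is the TAC
    measurement at time k tau.  Noise can push observations slightly negative,
    so no sign restriction is imposed on ``obs``.
    """

    id: str
    tau: float
    u: np.ndarray
    obs: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        obs = np.asarray(self.obs, dtype=float)
        if u.ndim != 1 or obs.shape != u.shape or len(u) < 1:
            raise ValueError(
                f"episode {self.id}: input and observation sequences must be equal-length "
                f"1-D arrays with at least one sample (got {u.shape} and {obs.shape})"
            )
        if self.tau <= 0:
            raise ValueError(f"episode {self.id}: tau must be positive")
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(obs))):
            raise ValueError(f"episode {self.id}: non-finite values")
        u = u.copy(); u.setflags(write=False)
        obs = obs.copy(); obs.setflags(write=False)
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "obs", obs)

    @property
    def n(self) -> int:
        return len(self.u)

    @property
    def times(self) -> np.ndarray:
        """Observation times k tau, k = 1..n."""
        return self.tau * np.arange(1, self.n + 1)


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian measurement noise with known variance."""

    sigma2: float = 1e-6

    def __post_init__(self) -> None:
        if self.sigma2 <= 0:
            raise ValueError(f"noise variance must be positive, got {self.sigma2}")

    def log_density(self, residuals: np.ndarray) -> float:
        r = np.asarray(residuals, dtype=float)
        n = r.size
        return -0.5 * n * math.log(2.0 * math.pi * self.sigma2) - 0.5 * float(r @ r) / self.sigma2


class OperatorCache:
    """Memoized (q, tau, N) -> DiscreteTimeSystem map.

    The sampled operators depend only on the parameter node, the sampling
    interval and the discretization level, so one cache can be shared across
    episodes, fits and whole studies.
    """

    def __init__(self) -> None:
        self._store: dict[tuple, DiscreteTimeSystem] = {}

    def get(self, q, tau: float, N: int) -> DiscreteTimeSystem:
        q = as_param_vector(q)
        key = (q.q1, q.q2, float(tau), int(N))
        dsys = self._store.get(key)
        if dsys is None:
            dsys = time_discretize(assemble_galerkin(q, N), tau)
            self._store[key] = dsys
        return dsys

    def __len__(self) -> int:
        return len(self._store)


@dataclass(frozen=True)
class LogDensityMatrix:
    """m x M table of per-episode, per-node log-densities log f_i(Y_i; q_j)."""

    values: np.ndarray
    episode_ids: tuple
    grid: ParameterGrid
    N: int
    sigma2: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape != (len(self.episode_ids), self.grid.M):
            raise ValueError(f"log-density matrix shape {v.shape} does not match "
                             f"{len(self.episode_ids)} episodes x {self.grid.M} nodes")
        if not np.all(np.isfinite(v)):
            raise ValueError("log-density matrix has non-finite entries")
        v = v.copy(); v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]

    def subset(self, rows) -> "LogDensityMatrix":
        """Row restriction to a subset of episodes (shares the grid)."""
        rows = np.asarray(rows)
        return LogDensityMatrix(
            values=self.values[rows],
            episode_ids=tuple(self.episode_ids[i] for i in rows),
            grid=self.grid, N=self.N, sigma2=self.sigma2,
        )


def subject_log_density(ep: Episode, q, N: int, noise: NoiseModel,
                        cache: OperatorCache | None = None) -> float:
    """log f(Y_ep; q): Gaussian log-density of the episode residuals.

    Simulates the TAC output from zero initial state and sums the pointwise
    normal log-densities of obs_k - y_k(q).
    """
    dsys = (cache or OperatorCache()).get(q, ep.tau, N)
    g = impulse_response(dsys, ep.n)
    y = simulate_output_convolution(g, ep.u)
    if not np.all(np.isfinite(y)):
        q = as_param_vector(q)
        raise FloatingPointError(
            f"forward simulation produced non-finite output at q=({q.q1}, {q.q2}), N={N}")
    return noise.log_density(ep.obs - y)


def build_log_density_matrix(episodes, grid: ParameterGrid, N: int, noise: NoiseModel,
                             cache: OperatorCache | None = None) -> LogDensityMatrix:
    """Evaluate every episode's log-density at every grid node.

    The sampled-data operators for a node are computed once per distinct tau
    and reused across episodes; with zero initial state each episode's output
    is the convolution of the node's impulse response with its BrAC input.
    """
    episodes = list(episodes)
    if not episodes:
        raise ValueError("need at least one episode")
    if grid.M < 1:
        raise ValueError("grid is empty")
    cache = cache or OperatorCache()

    # Group episode indices by tau so each node's impulse response is built
    # once per distinct sampling interval.
    by_tau: dict[float, list[int]] = {}
    for i, ep in enumerate(episodes):
        by_tau.setdefault(float(ep.tau), []).append(i)

    L = np.empty((len(episodes), grid.M))
    for j in range(grid.M):
        qj = grid.nodes[j]
        for tau, idxs in by_tau.items():
            dsys = cache.get(qj, tau, N)
            g = impulse_response(dsys, max(episodes[i].n for i in idxs))
            for i in idxs:
                ep = episodes[i]
                y = simulate_output_convolution(g, ep.u)
                L[i, j] = noise.log_density(ep.obs - y)
    return LogDensityMatrix(values=L, episode_ids=tuple(ep.id for ep in episodes),
                            grid=grid, N=int(N), sigma2=noise.sigma2)


def mixture_loglik(L, p) -> float:
    """sum_i logsumexp_j(log p_j + L[i, j]); zero weights contribute -inf terms.

    Raises DegenerateLikelihoodError if some episode's inner sum is empty
    (all weight on -inf terms).
    """
    Lv = L.values if isinstance(L, LogDensityMatrix) else np.asarray(L, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
    terms = logsumexp(Lv + logp[None, :], axis=1)
    if np.any(np.isneginf(terms)):
        bad = int(np.flatnonzero(np.isneginf(terms))[0])
        raise DegenerateLikelihoodError(
            f"episode index {bad} has zero mixture density under the given weights")
    return float(terms.sum())
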