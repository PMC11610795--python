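"""Discrete probability measures on a fixed parameter grid.

The NPML estimator searches over convex combinations of Dirac measures
P = sum_j p_j delta_{q_j} supported on a fixed uniform meshgrid {q_j} in the
parameter rectangle.  This module provides the grid, the measure container,
the product-Beta reference law used in simulation studies, sampling, weighted
moments, the Dirac-pair Prohorov distance min(d, 1), and the discrepancy
statistics D, D_bar_M, D_bar_N comparing estimated and true distribution
functions at the grid nodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import betainc
from scipy.stats import beta as beta_dist

from .params import ParamDomain, ParamVector, as_param_vector

__all__ = [
    "ParameterGrid",
    "DiscreteMeasure",
    "ProductBeta",
    "measure_cdf",
    "product_beta_cdf",
    "sample_measure",
    "dirac_prohorov",
    "discrepancy_D",
    "normalized_discrepancies",
    "measure_moments",
]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class ParameterGrid:
    """Uniform m1 x m2 meshgrid of parameter nodes, row-major in q1 then q2.

    Node j = i1 * m2 + i2 is (q1_vals[i1], q2_vals[i2]) with the axis values
    evenly spaced over the closed domain bounds.
    """

    domain: ParamDomain
    m1: int
    m2: int
    nodes: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.m1 < 1 or self.m2 < 1:
            raise ValueError(f"grid needs at least one node per axis, got {self.m1}x{self.m2}")
        q1v = np.linspace(self.domain.q1_lo, self.domain.q1_hi, self.m1)
        q2v = np.linspace(self.domain.q2_lo, self.domain.q2_hi, self.m2)
        g1, g2 = np.meshgrid(q1v, q2v, indexing="ij")
        nodes = np.column_stack([g1.ravel(), g2.ravel()])
        nodes.setflags(write=False)
        object.__setattr__(self, "nodes", nodes)

    @property
    def M(self) -> int:
        return self.m1 * self.m2

    def node(self, j: int) -> ParamVector:
        return ParamVector(*self.nodes[j])

    def nearest_index(self, q) -> int:
        q = as_param_vector(q)
        d = np.abs(self.nodes[:, 0] - q.q1) + np.abs(self.nodes[:, 1] - q.q2)
        return int(np.argmin(d))

    def spacing(self) -> tuple[float, float]:
        """Grid step along each axis (0 for a single-node axis)."""
        d1 = (self.domain.q1_hi - self.domain.q1_lo) / (self.m1 - 1) if self.m1 > 1 else 0.0
        d2 = (self.domain.q2_hi - self.domain.q2_lo) / (self.m2 - 1) if self.m2 > 1 else 0.0
        return d1, d2

    def to_dict(self) -> dict:
        d = self.domain
        return {
            "q1_lo": d.q1_lo, "q1_hi": d.q1_hi, "q2_lo": d.q2_lo, "q2_hi": d.q2_hi,
            "metric_order": d.metric_order, "m1": self.m1, "m2": self.m2,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterGrid":
        dom = ParamDomain(d["q1_lo"], d["q1_hi"], d["q2_lo"], d["q2_hi"],
                          d.get("metric_order", 2.0))
        return cls(dom, int(d["m1"]), int(d["m2"]))


@dataclass(frozen=True)
class DiscreteMeasure:
    """Probability measure sum_j p_j delta_{q_j} on a ParameterGrid."""

    grid: ParameterGrid
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (self.grid.M,):
            raise ValueError(f"weights shape {w.shape} does not match grid size {self.grid.M}")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"weights must sum to 1 within {_WEIGHT_TOL}, got {w.sum()!r}")
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "weights", w)

    @classmethod
    def atom(cls, grid: ParameterGrid, j: int) -> "DiscreteMeasure":
        w = np.zeros(grid.M)
        w[j] = 1.0
        return cls(grid, w)

    @classmethod
    def atoms(cls, grid: ParameterGrid, indices, weights) -> "DiscreteMeasure":
        w = np.zeros(grid.M)
        for j, pj in zip(indices, weights):
            w[j] += pj
        return cls(grid, w)

    @classmethod
    def uniform(cls, grid: ParameterGrid) -> "DiscreteMeasure":
        return cls(grid, np.full(grid.M, 1.0 / grid.M))

    def cdf(self, point) -> float:
        return measure_cdf(self, point)

    def sample(self, n: int, seed=None) -> np.ndarray:
        return sample_measure(self, n, seed)

    def to_json(self) -> str:
        payload = {"grid": self.grid.to_dict(), "weights": [repr(float(w)) for w in self.weights]}
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "DiscreteMeasure":
        payload = json.loads(s)
        grid = ParameterGrid.from_dict(payload["grid"])
        w = np.array([float(x) for x in payload["weights"]])
        return cls(grid, w)


@dataclass(frozen=True)
class ProductBeta:
    """Product law with both coordinates i.i.d. Beta(alpha, beta) on [0, 1]."""

    alpha: float = 2.0
    beta: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shape parameters must be positive")

    def cdf(self, point) -> float:
        return product_beta_cdf(self, point)

    def sample(self, n: int, seed=None) -> np.ndarray:
        rng = np.random.default_rng(seed)
        return rng.beta(self.alpha, self.beta, size=(n, 2))


def measure_cdf(P: DiscreteMeasure, point) -> float:
    """F(point) = sum of weights of nodes dominated componentwise (closed orthant)."""
    q = as_param_vector(point)
    nodes = P.grid.nodes
    mask = (nodes[:, 0] <= q.q1) & (nodes[:, 1] <= q.q2)
    return float(P.weights[mask].sum())


def product_beta_cdf(pb: ProductBeta, point) -> float:
    """Joint cdf of the product law: F(q1) F(q2), coordinates clipped to [0, 1]."""
    q = as_param_vector(point)
    x1 = min(max(q.q1, 0.0), 1.0)
    x2 = min(max(q.q2, 0.0), 1.0)
    return float(betainc(pb.alpha, pb.beta, x1) * betainc(pb.alpha, pb.beta, x2))


def sample_measure(P: DiscreteMeasure, n: int, seed=None) -> np.ndarray:
    """n i.i.d. node draws with probabilities p_j; returns an (n, 2) array."""
    if n < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    idx = rng.choice(P.grid.M, size=n, p=P.weights)
    return P.grid.nodes[idx].copy()


def dirac_prohorov(qa, qb, d=None) -> float:
    """Prohorov distance between Dirac measures: min(d(qa, qb), 1).

    ``d`` is a callable metric on parameter pairs; defaults to the Euclidean
    (p = 2) metric.
    """
    if d is None:
        a = qa.as_tuple() if isinstance(qa, ParamVector) else tuple(qa)
        b = qb.as_tuple() if isinstance(qb, ParamVector) else tuple(qb)
        dist = float(np.hypot(a[0] - b[0], a[1] - b[1]))
    else:
        dist = float(d(qa, qb))
    return min(dist, 1.0)


def _cdf_at_all_nodes(P: DiscreteMeasure) -> np.ndarray:
    """Vectorized F_P(q_j) for every grid node via a 2-D cumulative sum."""
    w = P.weights.reshape(P.grid.m1, P.grid.m2)
    return np.cumsum(np.cumsum(w, axis=0), axis=1).ravel()


def discrepancy_D(P: DiscreteMeasure, truth) -> float:
    """Sum over grid nodes of squared cdf differences between P and the truth.

    ``truth`` is anything exposing ``cdf(point)`` (a ProductBeta or another
    DiscreteMeasure on any grid).
    """
    Fhat = _cdf_at_all_nodes(P)
    if isinstance(truth, ProductBeta):
        q1v = np.clip(P.grid.nodes[:, 0], 0.0, 1.0)
        q2v = np.clip(P.grid.nodes[:, 1], 0.0, 1.0)
        F0 = betainc(truth.alpha, truth.beta, q1v) * betainc(truth.alpha, truth.beta, q2v)
    else:
        F0 = np.array([truth.cdf(node) for node in P.grid.nodes])
    return float(np.sum((Fhat - F0) ** 2))


def normalized_discrepancies(D: float, M: int, N: int) -> tuple[float, float]:
    """(D_bar_M, D_bar_N) = (D / M, D / N): per-node and per-discretization-level
    normalizations of the squared-difference sum."""
    if M < 1 or N < 1:
        raise ValueError("normalizers must be positive integers")
    return D / M, D / N


def measure_moments(P: DiscreteMeasure):
    """Weighted mean, 2x2 covariance and correlation of a discrete measure.

    Correlation is defined as 0 when either marginal variance vanishes.
    """
    nodes = P.grid.nodes
    w = P.weights
    mean = w @ nodes
    centered = nodes - mean
    cov = (centered * w[:, None]).T @ centered
    v1, v2 = cov[0, 0], cov[1, 1]
    corr = 0.0 if v1 <= 0 or v2 <= 0 else float(cov[0, 1] / np.sqrt(v1 * v2))
    return mean, cov, corr


def beta_marginal_stats(pb: ProductBeta) -> tuple[float, float]:
    """Mean and variance of one Beta(alpha, beta) coordinate."""
    m = beta_dist.mean(pb.alpha, pb.beta)
    v = beta_dist.var(pb.alpha, pb.beta)
    return float(m), float(v)
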