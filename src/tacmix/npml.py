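"""Nonparametric maximum likelihood over the simplex on a fixed grid.

The decision variable is the weight vector p of a discrete mixing measure on
fixed grid nodes; the objective sum_i log sum_j p_j exp(L[i,j]) is concave in
p, so any local maximizer is global.  The primary solver is fixed-support EM
(monotone, exactly simplex-feasible, no step-size tuning); a
projected-constrained mode solving the same log-sum-exp program with SLSQP is
provided as an independent cross-check of the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .likelihood import DegenerateLikelihoodError, LogDensityMatrix, mixture_loglik
from .measures import DiscreteMeasure

__all__ = ["SolverConfig", "NPMLFit", "em_step", "fit_npml", "support_points"]

_TRUNCATE = 1e-12


@dataclass(frozen=True)
class SolverConfig:
    """Optimizer settings for the simplex-constrained likelihood maximization."""

    method: str = "em"              # "em" or "projected-constrained"
    tol: float = 1e-8               # absolute log-likelihood change to stop
    max_iter: int = 5000
    weight_floor: float = 1e-3      # support-reporting threshold

    def __post_init__(self) -> None:
        if self.method not in ("em", "projected-constrained"):
            raise ValueError(f"unknown solver method {self.method!r}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValueError("tol must be positive and max_iter at least 1")


@dataclass(frozen=True)
class NPMLFit:
    """Fitted mixing measure with its log-likelihood and solver trace."""

    measure: DiscreteMeasure
    loglik: float
    iterations: int
    converged: bool
    trajectory: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "weights": [repr(w) for w in self.measure.weights],
            "grid": self.measure.grid.to_dict(),
            "loglik": self.loglik,
            "iterations": self.iterations,
            "converged": self.converged,
            "trajectory": list(self.trajectory),
        }


def _log_posteriors(Lv: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-normalized log responsibilities log w_{ij} in the log domain."""
    with np.errstate(divide="ignore"):
        logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
    a = Lv + logp[None, :]
    rows = logsumexp(a, axis=1)
    if np.any(np.isneginf(rows)):
        bad = int(np.flatnonzero(np.isneginf(rows))[0])
        raise DegenerateLikelihoodError(f"episode index {bad} has a degenerate posterior row")
    return a - rows[:, None]


def em_step(L, p) -> np.ndarray:
    """One fixed-support EM update: p'_j = mean_i of the posterior P(node j | episode i)."""
    Lv = L.values if isinstance(L, LogDensityMatrix) else np.asarray(L, dtype=float)
    p = np.asarray(p, dtype=float)
    w = np.exp(_log_posteriors(Lv, p))
    p_new = w.mean(axis=0)
    return p_new / p_new.sum()


def _fit_em(Lv: np.ndarray, cfg: SolverConfig):
    M = Lv.shape[1]
    p = np.full(M, 1.0 / M)
    traj = [mixture_loglik(Lv, p)]
    converged = False
    for _ in range(cfg.max_iter):
        p = em_step(Lv, p)
        traj.append(mixture_loglik(Lv, p))
        if abs(traj[-1] - traj[-2]) < cfg.tol:
            converged = True
            break
    return p, np.array(traj), converged


def _fit_projected(Lv: np.ndarray, cfg: SolverConfig):
    """Generic constrained maximization of the log-sum-exp objective (SLSQP)."""
    m, M = Lv.shape

    def neg_obj_and_grad(p):
        p = np.clip(p, 0.0, None)
        with np.errstate(divide="ignore"):
            logp = np.where(p > 0, np.log(np.where(p > 0, p, 1.0)), -np.inf)
        a = Lv + logp[None, :]
        rows = logsumexp(a, axis=1)
        # d/dp_j sum_i log sum_l p_l e^{L_il} = sum_i e^{L_ij - rows_i}
        grad = np.exp(Lv - rows[:, None]).sum(axis=0)
        return -rows.sum(), -grad

    traj: list[float] = []
    x0 = np.full(M, 1.0 / M)
    res = minimize(
        neg_obj_and_grad, x0, jac=True, method="SLSQP",
        bounds=[(0.0, 1.0)] * M,
        constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                      "jac": lambda p: np.ones_like(p)}],
        callback=lambda p: traj.append(mixture_loglik(Lv, np.clip(p, 0, None) / np.clip(p, 0, None).sum())),
        options={"maxiter": cfg.max_iter, "ftol": cfg.tol},
    )
    p = np.clip(res.x, 0.0, None)
    p /= p.sum()
    traj.append(mixture_loglik(Lv, p))
    return p, np.array(traj), bool(res.success), res.nit


def fit_npml(L, cfg: SolverConfig | None = None) -> NPMLFit:
    """Maximize the mixture log-likelihood over the simplex on L's grid.

    Starts from uniform weights; for the concave objective the optimum is
    initialization-independent and uniform makes ties deterministic.  Weights
    below 1e-12 are truncated and the vector renormalized on exit.
    """
    cfg = cfg or SolverConfig()
    if not isinstance(L, LogDensityMatrix):
        raise TypeError("fit_npml expects a LogDensityMatrix (use em_step for raw arrays)")
    Lv = L.values

    if cfg.method == "em":
        p, traj, converged = _fit_em(Lv, cfg)
        iterations = len(traj) - 1
    else:
        p, traj, converged, iterations = _fit_projected(Lv, cfg)

    p = np.where(p < _TRUNCATE, 0.0, p)
    p /= p.sum()
    return NPMLFit(
        measure=DiscreteMeasure(L.grid, p),
        loglik=mixture_loglik(Lv, p),
        iterations=iterations,
        converged=converged,
        trajectory=traj,
    )


def support_points(fit: NPMLFit, floor: float | None = None):
    """Nodes carrying weight above the floor, sorted by weight descending."""
    if floor is None:
        floor = 1e-3
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    w = fit.measure.weights
    idx = np.flatnonzero(w > floor)
    order = idx[np.argsort(-w[idx], kind="stable")]
    nodes = fit.measure.grid.nodes
    return [(tuple(nodes[j]), float(w[j])) for j in order]
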