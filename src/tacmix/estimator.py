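"""Scikit-learn style front end for the NPML mixing-distribution estimator.

``NPMLDistributionEstimator.fit`` takes a list of :class:`~tacmix.likelihood.Episode`
objects (one drinking episode each), evaluates every episode's log-density on
a fixed parameter grid through the Galerkin forward solver, and maximizes the
mixture log-likelihood over the simplex.  The fitted mixing measure and its
summaries are exposed as trailing-underscore attributes; the class composes
with sklearn's ``clone``/``get_params``/``set_params`` machinery.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .likelihood import (
    Episode,
    NoiseModel,
    OperatorCache,
    build_log_density_matrix,
    mixture_loglik,
)
from .measures import ParameterGrid, measure_moments
from .npml import SolverConfig, fit_npml, support_points
from .params import ParamDomain
from .pde import impulse_response, simulate_output_convolution

__all__ = ["NPMLDistributionEstimator"]


class NPMLDistributionEstimator(BaseEstimator):
    """Nonparametric MLE of the (q1, q2) mixing distribution on a fixed grid.

    Parameters
    ----------
    q1_lo, q1_hi, q2_lo, q2_hi : float
        Bounds of the compact parameter rectangle Q.
    m1, m2 : int
        Grid nodes per axis; the grid has M = m1 * m2 Dirac support points.
    N : int
        Spatial discretization level (linear-spline sub-intervals).
    sigma2 : float
        Known measurement-noise variance of the Gaussian observation model.
    method : {"em", "projected-constrained"}
        Simplex solver; both maximize the same concave objective.
    tol, max_iter : float, int
        Stopping rule on the absolute log-likelihood change.
    weight_floor : float
        Reporting threshold for :meth:`support_`.

    Attributes
    ----------
    grid_ : ParameterGrid
    measure_ : DiscreteMeasure            fitted mixing measure
    weights_ : ndarray of shape (M,)
    loglik_ : float
    n_iter_ : int
    converged_ : bool
    log_density_ : LogDensityMatrix      episode x node log-density table
    """

    def __init__(self, q1_lo=0.05, q1_hi=1.0, q2_lo=0.05, q2_hi=1.0,
                 m1=20, m2=20, N=128, sigma2=1e-6,
                 method="em", tol=1e-8, max_iter=5000, weight_floor=1e-3):
        self.q1_lo = q1_lo
        self.q1_hi = q1_hi
        self.q2_lo = q2_lo
        self.q2_hi = q2_hi
        self.m1 = m1
        self.m2 = m2
        self.N = N
        self.sigma2 = sigma2
        self.method = method
        self.tol = tol
        self.max_iter = max_iter
        self.weight_floor = weight_floor

    # -- sklearn-style API -------------------------------------------------

    def fit(self, X, y=None, cache: OperatorCache | None = None):
        """Fit the mixing distribution to a list of episodes.

        ``X`` is a sequence of :class:`Episode`; ``y`` is ignored (present for
        API compatibility).  An optional :class:`OperatorCache` lets repeated
        fits on the same grid share the sampled-data operators.
        """
        episodes = self._check_episodes(X)
        self.grid_ = ParameterGrid(
            ParamDomain(self.q1_lo, self.q1_hi, self.q2_lo, self.q2_hi),
            int(self.m1), int(self.m2))
        noise = NoiseModel(self.sigma2)
        self._cache = cache or OperatorCache()
        self.log_density_ = build_log_density_matrix(
            episodes, self.grid_, int(self.N), noise, cache=self._cache)
        fit = fit_npml(self.log_density_, SolverConfig(
            method=self.method, tol=self.tol, max_iter=self.max_iter,
            weight_floor=self.weight_floor))
        self.measure_ = fit.measure
        self.weights_ = fit.measure.weights
        self.loglik_ = fit.loglik
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        self.trajectory_ = fit.trajectory
        return self

    def score(self, X, y=None) -> float:
        """Mixture log-likelihood of new episodes under the fitted measure."""
        self._check_fitted()
        episodes = self._check_episodes(X)
        L = build_log_density_matrix(
            episodes, self.grid_, int(self.N), NoiseModel(self.sigma2), cache=self._cache)
        return mixture_loglik(L, self.weights_)

    def sample(self, n: int, seed=None) -> np.ndarray:
        """Draw n parameter vectors from the fitted mixing measure."""
        self._check_fitted()
        return self.measure_.sample(n, seed)

    def predict_tac(self, episode: Episode) -> np.ndarray:
        """Population-expected TAC curve for an episode's BrAC input.

        Returns sum_j p_j y(q_j), the mixture mean of the forward outputs.
        """
        self._check_fitted()
        y = np.zeros(episode.n)
        for j in np.flatnonzero(self.weights_ > 0):
            dsys = self._cache.get(self.grid_.nodes[j], episode.tau, int(self.N))
            g = impulse_response(dsys, episode.n)
            y += self.weights_[j] * simulate_output_convolution(g, episode.u)
        return y

    # -- summaries ---------------------------------------------------------

    def support_(self):
        """(node, weight) pairs above the weight floor, heaviest first."""
        self._check_fitted()
        from .npml import NPMLFit
        fit = NPMLFit(self.measure_, self.loglik_, self.n_iter_,
                      self.converged_, self.trajectory_)
        return support_points(fit, self.weight_floor)

    def moments_(self):
        """Weighted mean vector, covariance matrix and correlation."""
        self._check_fitted()
        return measure_moments(self.measure_)

    # -- helpers -----------------------------------------------------------

    @staticmethod
    def _check_episodes(X) -> list[Episode]:
        episodes = list(X)
        if not episodes:
            raise ValueError("need at least one episode")
        for ep in episodes:
            if not isinstance(ep, Episode):
                raise TypeError(f"expected Episode objects, got {type(ep).__name__}")
        return episodes

    def _check_fitted(self) -> None:
        if not hasattr(self, "measure_"):
            raise AttributeError("estimator is not fitted; call fit() first")
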