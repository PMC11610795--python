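"""Forward model: 1-D diffusion of ethanol through the epidermal layer.

The dimensionless model on the unit interval (skin surface at eta = 0,
epidermal/dermal boundary at eta = 1) is

    x_t = q1 x_etaeta,           0 < eta < 1,
    q1 x_eta(t, 0) = x(t, 0),    evaporation at the skin surface,
    q1 x_eta(t, 1) = q2 u(t),    BrAC-driven flux from the dermal side,
    x(0, .) = 0,                 no alcohol in the skin at t = 0,
    y(t) = x(t, 0),              TAC read at the surface.

This module semi-discretizes the weak form in space with linear splines (hat
functions) on the uniform mesh {0, 1/N, ..., 1} and then discretizes in time
exactly under a zero-order hold on the input, giving the sampled-data system

    x_k = Ahat x_{k-1} + Bhat u_{k-1},    y_k = chat . x_k,

with Ahat = exp(A tau), Bhat = int_0^tau exp(A s) ds B, A = -M^-1 K,
B = M^-1 b.  Basis ordering puts spline index 0 at the skin surface, so the
output functional selects coefficient 0 and the load vector hits coefficient N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .params import ParamVector, as_param_vector

__all__ = [
    "GalerkinSystem",
    "DiscreteTimeSystem",
    "assemble_galerkin",
    "time_discretize",
    "simulate_output",
    "impulse_response",
    "simulate_output_convolution",
    "steady_state_output",
]


@dataclass(frozen=True)
class GalerkinSystem:
    """Spatial Galerkin discretization for one parameter vector.

    mass[j,k]      = int phi_j phi_k
    stiffness[j,k] = q1 int phi_j' phi_k' + phi_j(0) phi_k(0)
    load[j]        = q2 phi_j(1)
    output[j]      = phi_j(0)
    """

    N: int
    mass: np.ndarray
    stiffness: np.ndarray
    load: np.ndarray
    output: np.ndarray
    param: ParamVector


@dataclass(frozen=True)
class DiscreteTimeSystem:
    """Exact zero-order-hold discretization (Ahat, Bhat, chat) at interval tau."""

    Ahat: np.ndarray
    Bhat: np.ndarray
    chat: np.ndarray
    tau: float

    @property
    def dim(self) -> int:
        return self.Ahat.shape[0]


def assemble_galerkin(q, N: int) -> GalerkinSystem:
    """Assemble mass/stiffness/load/output for hat functions on {j/N}.

    Raises on non-positive parameters or N < 1.
    """
    q = as_param_vector(q)
    N = int(N)
    if N < 1:
        raise ValueError(f"need at least one sub-interval, got N={N}")
    h = 1.0 / N

    # Tridiagonal mass matrix of linear splines: h/3 at the two boundary
    # diagonal entries, 2h/3 in the interior, h/6 off-diagonal.
    diag = np.full(N + 1, 2.0 * h / 3.0)
    diag[0] = diag[-1] = h / 3.0
    off = np.full(N, h / 6.0)
    mass = np.diag(diag) + np.diag(off, 1) + np.diag(off, -1)

    # Stiffness: q1 * (gradient form) + boundary evaporation term at eta=0.
    sdiag = np.full(N + 1, 2.0 / h)
    sdiag[0] = sdiag[-1] = 1.0 / h
    soff = np.full(N, -1.0 / h)
    stiffness = q.q1 * (np.diag(sdiag) + np.diag(soff, 1) + np.diag(soff, -1))
    stiffness[0, 0] += 1.0

    load = np.zeros(N + 1)
    load[N] = q.q2
    output = np.zeros(N + 1)
    output[0] = 1.0
    return GalerkinSystem(N=N, mass=mass, stiffness=stiffness, load=load, output=output, param=q)


def time_discretize(sys: GalerkinSystem, tau: float) -> DiscreteTimeSystem:
    """Exact sampled-data operators under a zero-order hold.

    Bhat is obtained from the augmented block exponential
    exp([[A, B], [0, 0]] tau) = [[Ahat, Bhat], [0, I]], which avoids
    inverting A and is exact for the hold input.
    """
    tau = float(tau)
    if tau <= 0:
        raise ValueError(f"sampling interval must be positive, got tau={tau}")
    n = sys.N + 1
    # A = -M^-1 K, B = M^-1 b via solves; never an explicit inverse.
    A = np.linalg.solve(sys.mass, -sys.stiffness)
    B = np.linalg.solve(sys.mass, sys.load)
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = A
    aug[:n, n] = B
    E = expm(aug * tau)
    return DiscreteTimeSystem(Ahat=E[:n, :n], Bhat=E[:n, n], chat=sys.output.copy(), tau=tau)


def simulate_output(dsys: DiscreteTimeSystem, u, x0=None) -> np.ndarray:
    """March the sampled system, returning y_k = chat.x_k for k = 1..len(u).

    u[k-1] is held on [(k-1) tau, k tau); the k-th output sample is read at
    time k tau.  Default initial state is zero (alcohol-free skin).
    """
    u = np.asarray(u, dtype=float)
    n = dsys.dim
    if x0 is None:
        x = np.zeros(n)
    else:
        x = np.asarray(x0, dtype=float)
        if x.shape != (n,):
            raise ValueError(f"x0 has shape {x.shape}, system dimension is {n}")
    y = np.empty(len(u))
    for k in range(len(u)):
        x = dsys.Ahat @ x + dsys.Bhat * u[k]
        y[k] = dsys.chat @ x
    return y


def impulse_response(dsys: DiscreteTimeSystem, K: int) -> np.ndarray:
    """First K Markov parameters g_j = chat . Ahat^j . Bhat, j = 0..K-1."""
    g = np.empty(K)
    v = dsys.Bhat.copy()
    for j in range(K):
        g[j] = dsys.chat @ v
        if j + 1 < K:
            v = dsys.Ahat @ v
    return g


def simulate_output_convolution(g: np.ndarray, u) -> np.ndarray:
    """Zero-initial-state output via convolution with the impulse response.

    Equivalent to :func:`simulate_output` with x0 = 0:
    y_k = sum_{l=0}^{k-1} g_{k-1-l} u_l.
    """
    u = np.asarray(u, dtype=float)
    K = len(u)
    return np.convolve(g[:K], u)[:K]


def steady_state_output(q, u_const: float) -> float:
    """Analytic equilibrium TAC under a constant BrAC input.

    The stationary profile solves q1 x'' = 0 with the two flux boundary
    conditions, giving x(eta) = q2 u (1 + eta/q1) and hence y = x(0) = q2 u.
    Serves as a closed-form oracle for the solver.
    """
    q = as_param_vector(q)
    return q.q2 * float(u_const)
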