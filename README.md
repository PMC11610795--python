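# tacmix

Nonparametric mixed-effects estimation of random-parameter distributions for a
one-dimensional diffusion model of transdermal alcohol transport.

Transdermal alcohol biosensors measure transdermal alcohol concentration (TAC)
at the skin surface, which is related to breath alcohol concentration (BrAC)
through transport of ethanol across the epidermal layer. In dimensionless
variables the transport model is

    x_t(t, η) = q1 x_ηη(t, η),        0 < η < 1,
    q1 x_η(t, 0) = x(t, 0),           evaporation at the skin surface,
    q1 x_η(t, 1) = q2 u(t),           BrAC-driven flux at the dermal boundary,
    x(0, ·) = 0,     y(t) = x(t, 0),

where `u` is BrAC, `y` is TAC, and q = (q1, q2) — the normalized diffusivity
and flux gain — varies across people, devices and drinking episodes.  tacmix
treats q as random across episodes and estimates its *distribution* by
nonparametric maximum likelihood (NPML): given m drinking episodes with
observations `Y_{k,i} = y_k(q_i) + e_{k,i}`, `e_{k,i} ~ N(0, σ²)`, it maximizes
the mixture log-likelihood

    Σ_i log Σ_j p_j exp( log f_i(Y_i; q_j) )

over probability weights `p` on a fixed grid of nodes `{q_j}`.  The forward
map is a linear-spline Galerkin semi-discretization of the PDE combined with
an exact zero-order-hold time discretization (`Â = e^{Aτ}`,
`B̂ = ∫₀^τ e^{As} ds B`); the objective is concave in `p` and is maximized
with fixed-support EM (a generic constrained solver is available as a
cross-check).  The fitted object is a discrete mixing measure
`P̂ = Σ_j p_j δ_{q_j}` whose support, moments and predictive TAC bands are the
quantities of scientific interest.

Intended users: researchers in alcohol biosensor modeling and, more broadly,
anyone estimating a random-parameter distribution of a dynamical model from
longitudinal panels on a fixed parameter grid.

## Worked example

```python
import numpy as np
from tacmix import (DiscreteMeasure, NPMLDistributionEstimator, ParamDomain,
                    ParameterGrid, PopulationSpec, generate_population)

# a synthetic panel: 20 episodes whose (q1, q2) come from two atoms
grid = ParameterGrid(ParamDomain(), 20, 20)
truth = DiscreteMeasure.atoms(
    grid, [grid.nearest_index((0.3, 0.4)), grid.nearest_index((0.6, 0.75))],
    [0.3, 0.7])
episodes, _ = generate_population(
    PopulationSpec(m=20, truth=truth, sigma2=1e-6, N_sim=64, seed=1))

est = NPMLDistributionEstimator(m1=20, m2=20, N=64, sigma2=1e-6)
est.fit(episodes)
print("log-likelihood:", round(est.loglik_, 1))
for node, w in est.support_():
    print(f"  atom at q1={node[0]:.2f}, q2={node[1]:.2f}  weight {w:.3f}")
mean, cov, corr = est.moments_()
print("mean:", np.round(mean, 3), " correlation:", round(corr, 3))
```

Output:

```
log-likelihood: 13180.9
  atom at q1=0.60, q2=0.75  weight 0.650
  atom at q1=0.30, q2=0.40  weight 0.350
mean: [0.495 0.628]  correlation: 1.0
```

The estimator recovers the two generating atoms with their empirical weights
(7 of the 20 episodes came from the first atom).  The printed mean and
correlation are the weighted moments of the fitted mixing measure.

The same workflow is available from the shell:

```bash
tacmix simulate --m 20 --seed 1 --out episodes.csv
tacmix fit --episodes episodes.csv --N 64 --out fit.json
tacmix consistency --m 1,5,20 --seed 1 --N 64 --out D_table.csv
tacmix loocv --episodes episodes.csv --N 64 --seed 1 --out loocv.json
```

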