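# Methods

## Model

Ethanol transport through the epidermal layer is modeled, in dimensionless
variables, as one-dimensional diffusion on the unit interval with a Robin
(evaporation) boundary condition at the skin surface (η = 0) and a
BrAC-driven flux condition at the epidermal/dermal boundary (η = 1):

    x_t = q1 x_ηη,   q1 x_η(t,0) = x(t,0),   q1 x_η(t,1) = q2 u(t),
    x(0,·) = 0,      y(t) = x(t,0).

The two parameters — the normalized diffusivity q1 and the normalized flux
gain q2 — are positive, dimensionless, and treated as *random across drinking
episodes*: episode i carries its own q_i, drawn i.i.d. from an unknown mixing
distribution P supported on a compact rectangle Q. Observations are

    Y_{k,i} = y_k(q_i) + e_{k,i},   k = 1..n_i,   e_{k,i} ~ N(0, σ²) i.i.d.,

with σ² known. The estimand is P itself; no parametric family is assumed for
it (nonparametric maximum likelihood, NPML). By the classical support-size
result for mixture MLEs, the NPML optimum over all probability measures is a
discrete measure with at most m support points, which motivates restricting
the search to discrete measures P = Σ_j p_j δ_{q_j} on a fixed grid {q_j} and
optimizing only the weight vector p on the probability simplex.

## Forward solver

The weak form of the PDE is projected onto the span of linear splines (hat
functions) on the uniform mesh {0, 1/N, …, 1}. For basis functions φ_j this
gives the mass matrix M_jk = ∫φ_jφ_k, the stiffness form
K_jk = q1 ∫φ_j′φ_k′ + φ_j(0)φ_k(0), the load vector b_j = q2 φ_j(1) and the
output functional c_j = φ_j(0); index 0 sits at the skin surface so the
output reads coefficient 0 and the input flux drives coefficient N. Because
the stiffness quadratic form q1∫|ψ′|² + |ψ(0)|² is strictly positive for
ψ ≠ 0, the semi-discrete generator A = −M⁻¹K is Hurwitz and the sampled
dynamics are strictly stable.

Time discretization is exact for a zero-order-hold input held constant on
each interval [(k−1)τ, kτ): Â = e^{Aτ}, B̂ = ∫₀^τ e^{As} ds · B, read off
the augmented block exponential exp([[A, B],[0, 0]]τ) so that A is never
inverted. A is formed by column solves against M, never via an explicit
inverse. The k-th observation is taken at time kτ against the input held on
the preceding interval.

Numerical shortcut: with zero initial state the system is linear and
time-invariant, so each episode output is the convolution of the node's
impulse response g_j = ĉ·Â^j·B̂ with its input. The likelihood table
therefore costs one matrix exponential and one impulse response per (node, τ,
N), re-used across all episodes and all fits through an operator cache; this
is verified against the direct state recursion to float accumulation
accuracy (~1e-9 absolute on log-densities of magnitude ~1e3).

## Likelihood and optimizer

Per episode and grid node, the Gaussian log-density of the residuals is
accumulated in the log domain; the mixture objective
Σ_i log Σ_j exp(log p_j + L_ij) uses log-sum-exp, since at σ² = 1e-6 the raw
product of ~120 normal densities under- or overflows double precision. The
objective is concave in p, so every local maximizer on the simplex is global.

The primary solver is fixed-support EM: p′_j = (1/m) Σ_i P(node j | episode
i). It is monotone in the objective, stays exactly on the simplex, and needs
no step-size tuning. Stopping: absolute log-likelihood change < 1e-8
(default) or 5000 iterations; EM's sublinear tail means the default
tolerance locates the optimum to roughly 1e-6 in log-likelihood — use
tol ≈ 1e-11 where tighter agreement matters. A projected-constrained mode
(SLSQP on the same log-sum-exp objective with analytic gradient, simplex
equality constraint and box bounds) replicates the generic
constrained-optimizer route and serves as an independent cross-check; the
two agree to better than 1e-6 in log-likelihood on random instances. Weights
below 1e-12 are truncated and the vector renormalized on exit, giving clean
support reporting. Initialization is uniform: an interior simplex point that
makes tie-breaking deterministic (a constant log-density matrix returns the
uniform measure).

The grid stays fixed throughout (no adaptive refinement); support masses of
a continuous truth therefore split across adjacent nodes, which is why the
at-most-m support bound is checked statistically (fraction of replicates)
rather than asserted per fit, and why two-atom recovery is scored on
one-node neighborhoods of the generating atoms.

## Grid and discrepancy statistics

The default parameter domain is [0.05, 1] × [0.05, 1] with 20 uniformly
spaced nodes per axis (M = 400, nodes j/20). The lower bound is kept strictly
positive because q1 = 0 degenerates the diffusion (the stiffness form loses
coercivity and the sampled dynamics their strict stability); domain bounds
and node counts are configurable, and real-sensor fits may need q2 above 1.

Agreement between a fitted measure P̂ and a truth law P0 is summarized by

    D = Σ_{j=1}^M ( F̂(q_j) − F0(q_j) )²,

the sum over grid nodes of squared differences between the two cumulative
distribution functions (closed lower-orthant convention), with normalized
variants D̄_M = D/M for grid-refinement tables and D̄_N = D/N for
discretization-refinement tables. The truth may be the product-Beta law or
any discrete measure. For Dirac pairs the Prohorov metric reduces to
min(d(q, q′), 1), which is provided as a utility.

## Synthetic data

No lab BrAC recordings are distributable, so study inputs are emulated:
piecewise-linear single-peak BrAC profiles (linear rise to a peak, optional
plateau, linear decline, zero tail), with per-episode shape randomized
uniformly within configured ranges. Defaults, in dimensionless units chosen
once as representative of single-peak drinking-episode morphology: peak
∈ [0.05, 0.12], rise time ∈ [0.5, 2], plateau ∈ [0, 1], fall time ∈ [2, 6],
horizon 12, sampling interval τ = 0.1 (hence n = 120 samples per episode).
Subject parameters default to i.i.d. Beta(2, 5) per coordinate (the
consistency-study truth); any discrete measure can be substituted (atoms for
recovery experiments). Observations add i.i.d. N(0, 1e-6) noise; the small
variance reflects environmental perturbations (humidity, temperature, skin
moisture) on an otherwise deterministic sensor path. Structure (parameters,
profiles) and noise use separate seeded streams, so the noise-free panel at
a seed is exactly the noisy panel minus its noise.

The generator's statistical model is *identical* to the model the estimator
assumes (same forward map, same Gaussian noise), and by default data are
generated at the same discretization level used in fitting. Passing tests
therefore demonstrates internal consistency and recovery under the model's
own assumptions — not robustness to model misspecification, sensor drift,
autocorrelated noise, or multi-peak episodes. An inverse-crime toggle
(N_sim ≠ fit N) exists for robustness experiments.

## Studies

*Consistency.* One nested panel per seed: the m-episode fit uses the first m
episodes of the largest panel, so the D-versus-m trend is within one growing
dataset. Study defaults at desk scale: M = 400, N = 64, m ∈ {1, 5, 20, 40};
D at m = 1 lands in the tens and falls by an order of magnitude by m = 40,
with strongly negative rank correlation across replicate seeds.

*Refinement.* On one fixed panel (m = 16), D̄_M is tabulated across
M ∈ {25, 100, 225, 400} at fixed N, and D̄_N across N ∈ {4, 16, 64, 128} at
fixed M = 400.

*LOOCV.* Each episode is held out in turn; the measure is refitted on the
rest (the log-density table is computed once and row-subset, so the m fits
share all forward solves); 100 parameter vectors are drawn from the fitted
measure and posterior-predictive TAC curves are simulated from the held-out
episode's BrAC. Predictive curves include additive N(0, σ²) observation
noise: the band is meant to cover *measured* statistics, and the maximum of
~120 noisy samples is biased upward by roughly σ√(2 ln n) ≈ 3e-3, so
noise-free draws would systematically under-cover the peak statistic.
Bands are pointwise 2.5/97.5 percentiles (linear interpolation between order
statistics); each statistic's 95% interval is taken over the per-draw
statistics rather than read off the band curves. TAC statistics: peak value,
time of the first maximum (deterministic tie-break on plateaus), and
trapezoidal AUC on the observation grid. No smoothing is applied to measured
curves before peak-time comparison.

## Numerical choices and limitations

- Weight-vector validity (nonnegative, unit sum) is enforced to 1e-12 at
  construction; fitted weights are renormalized exactly on exit.
- Correlation of a degenerate (single-atom) measure is defined as 0.
- Episode CSV round trips are lossless (17-significant-digit floats,
  round-trip float parsing); measure JSON round trips are bit-stable.
- τ and the episode horizon are study configuration, not identified
  constants; all defaults are stated above.
- Known limitations: Gaussian homoscedastic noise only; σ² is supplied, not
  estimated; no adaptive grid; no BrAC-from-TAC deconvolution; coarse meshes
  (N ≤ 16) can undershoot zero by ~1e-10 (linear FEM is not positivity
  preserving).
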