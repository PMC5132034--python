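# Methods

## Model and optimality criterion

All computations assume the multivariate linear mixed effects model

    y_i(t) = α + a_i + (β + b_i) t + e_i(t),

with jointly normal random intercepts/slopes and multivariate normal
residuals, `Cov{b_i} = Σ_b`, `Cov{e_i(t)} = Σ_e` at fixed *t*.  Residual
autocorrelation, when present, is a single correlation function shared by all
tests: `Cov{e_ij(s), e_ij'(t)} = γ(|t−s|) · Σ_e[j,j']`.  This keeps the
composite's autocorrelation identical to the components' and guarantees a
positive definite `Γ_e(t)` for distinct visit times.

A weighted composite `z = w'y` follows a scalar LME with slope `w'β`,
random-slope variance `w'Σ_b w` and residual variance `w'Σ_e w`.  For a
design `t` the variance of an efficient estimate of the composite slope from
one subject is `w'Λ_t w` with `Λ_t = Σ_b + τ_e(t)Σ_e`, where
`τ_e(t) = [(X'Γ⁻¹X)⁻¹]₂₂`, `X = [1, t]`.  Maximizing `(w'β)²/(w'Λ_t w)` is a
generalized Rayleigh problem with closed-form solution `w ∝ Λ_t⁻¹β` and
maximum `β'Λ_t⁻¹β`.  The package treats this identification of the slope
variance with `w'Λ_t w` as exact for balanced complete data, where the
per-subject GLS slope achieves it; the simulator/estimator closure tests
verify it empirically (covariance of per-subject OLS slopes → Σ_b + τ_e Σ_e
within 2% at n = 50,000).  Fisher-information assembly for unbalanced data is
not implemented.

Because the optimum is a quadratic form in a positive definite matrix, the
composite slope at the optimal weights is always strictly positive after the
sign convention, but individual components may take weights opposing their
own test's slope; these negative weights are noise cancellation, not errors,
and the optimality proof is exercised numerically in the tests (random-search
and simplex-optimizer oracles never beat the closed form; agreement to 1e-10).

## Conventions and parameters

* **Time unit: years.**  Month-denominated durations in interfaces are
  converted exactly (months/12).  The UTD scheme is literally the `t = [0,1]`
  special case with the shared-autocorrelation assumption; the historical
  variant with per-test residual autocovariances is not implemented.
* **Normalization.**  `Σ_j|w_j| = 1` with `w'β > 0`.  The scale constant has
  no effect on any efficiency quantity; the convention exists so printed
  weights are comparable.  A user-supplied `w` with `w'β = 0` exactly is
  flagged (`slope_sign_ambiguous`) rather than silently signed.
* **Positive definiteness.**  Covariances must be symmetric (relative
  tolerance 1e-8, then symmetrized) and strictly PD (smallest eigenvalue
  > 1e-10 × largest).  Linear solves use Cholesky factorization, never
  explicit inverses; singular inputs raise rather than fall back to
  pseudo-inverses, since PD is a model assumption, not a numerical nuisance.
* **Autocorrelation families.**  `identity` (Γ = I) and `exponential`
  (γ(Δ) = exp(−λΔ), λ > 0).  Both satisfy γ(0) = 1 and positive definiteness.
  No recommendation is made between them; at the 6–12-month visit intervals
  typical of this field residual autocorrelation is plausibly negligible, and
  all shipped examples use the identity family.  Duplicate visit times are
  rejected (they make X rank-deficient at p = 2 and Γ singular for positive
  families).
* **Sample size.**  `n = 2(z_{1−α/2} + z_{power})² · w'Λw/(k·w'β)²` per arm,
  ceiling-rounded — the standard two-arm normal approximation, with the
  treatment effect expressed as a fraction k of the placebo composite slope.
  Ratios between designs/weights are independent of this plumbing choice.

## Synthetic data generator

`simulate_trial` draws balanced complete data.  The 2m×2m random-effects
covariance is assembled as diagonal blocks `Σ_a` (default `Σ_b`) and `Σ_b`
with cross block `C[j,j'] = corr_ab[j,j'] √(Σ_a[jj] Σ_b[j'j'])`; the default
`corr_ab = 0.5·corr(Σ_b)` gives each test an intercept–slope correlation of
0.5 and cross-test correlations of 0.5ρ where ρ is the corresponding slope
correlation — the convention of the stylized two-test configuration shipped
in `presets.bivariate_params` (β = [1,1], Σ_b = [[0.5, ρ], [ρ, 2.0]],
Σ_e = diag(2.0, 0.5), ρ ∈ {0.2, 0.5, 0.8}).  Residuals have the Kronecker
structure Γ ⊗ Σ_e, drawn as `L_Γ Z L_Σᵉ'`.  The assembled covariance is
PD-checked with the offending eigenvalue reported.

The generator emulates idealized trial data: balanced, complete, with exactly
linear subject trajectories, Gaussian effects and a common autocorrelation.
It does not emulate dropout or intermittent missingness, floor/ceiling
effects, visit-time jitter, non-Gaussian tails, or treatment arms.  Passing
tests therefore certify the mathematics and the estimator under the model's
own assumptions, not robustness to the ways real trial data violate them —
composites in particular require complete per-visit test batteries, and
incomplete data are rejected, not dropped.

## Summary-measures estimation

Full-likelihood doubly multivariate LME fitting is deliberately avoided
(convergence failures are common in practice); instead a method-of-moments
estimator from per-subject OLS lines is used, requiring p ≥ 3 visits:

* `β̂` — mean of subject slope vectors;
* `Σ̂_e[j,j'] = Σ_i Σ_k r_ijk r_ij'k / (n(p−2))` — pooled residual
  cross-products; under balance all tests share one hat matrix, so each fit
  absorbs two residual degrees of freedom and the divisor makes the diagonal
  unbiased;
* `Σ̂_b = Ĉov(slopes) − τ_e Σ̂_e` (sample covariance, n−1 denominator),
  projected to the nearest PSD matrix by clipping negative eigenvalues at
  zero, with a flag.  The projection is a small-sample event; its frequency
  vanishes as the pilot grows (monitored in tests).

Estimated weights reuse `Λ̂⁻¹β̂` for the *trial* design, which may differ
from the pilot design; `Λ̂ = Σ̂_b + τ_e(trial)Σ̂_e` is PD-re-checked before
the solve (the clip makes this the binding condition), and rare failures in
the Monte Carlo loop are counted and excluded rather than silently patched.

## Monte Carlo weight-estimation study

`run_mc` simulates pilots from known truth, estimates weights per replicate,
and scores each estimated composite under the *true* parameters against the
true best single test.  By optimality every replicate ratio is ≥ the
known-weight ratio `N_LME/N_best`, so the mean (Expected) and empirical 0.95
quantile (numpy's default linear, i.e. type-7, interpolation) isolate the
cost of estimation.  Per-replicate random streams are spawned from the master
seed (`SeedSequence.spawn`), so results are reproducible and independent of
batching.  The reference configuration is the two-test truth above with a
3-year annual-visit schedule `t = [0,1,2,3]` used for both pilot and trial;
the pilot schedule is configurable.  Default replicate count in the CLI is
10,000; the test suite and the acceptance script use 2,000 per cell, which
resolves the Expected column to well under ±0.01 (MC standard error of the
mean ≈ 0.0002–0.001 across cells) and the 0.95 quantile to within ±0.02.

## Numerical and degenerate-input choices

* Best-test ties (identical `Λ_jj/β_j²`) resolve to the lowest index with a
  warning; tests with `β_j = 0` are excluded from the argmin.
* `design_term` always evaluates the GLS matrix expression; under the
  identity family it additionally evaluates the closed form
  `1/Σ(t_k − t̄)²` and asserts agreement at 1e-12 relative, as a live
  cross-check of the linear algebra.
* Floats are carried in double precision end to end; JSON writers round to
  12 significant digits at the edge only.
* `efficiency_curve` reports +inf at grid points whose composite slope is
  exactly zero rather than erroring mid-curve.

## Known limitations

* Weights are optimal only under the stated LME assumptions; model
  misspecification (nonlinear trajectories, heteroscedastic visits) is out of
  scope.
* Unbalanced designs, missingness handling and in-trial weight estimation are
  not provided; the estimator rejects incomplete data by design.
* The change-from-baseline worked example is only as precise as its 2-dp
  published inputs; recomputed weights can differ from published values by up
  to ~0.03 at the longest durations for this reason.
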