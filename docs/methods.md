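# Methods

This note documents the models implemented in `siphtool`, the numerical
choices behind them, what the synthetic-data scenarios emulate, and the
known limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model class

A transient Markov jump process on states `{1, …, p}` with initial
distribution `π` and sub-intensity matrix `T` has phase-type absorption
time `Z`. The SIPH class modulates the generator to `Θ λ(t) T`:

* `λ(t)` is a deterministic baseline intensity with cumulative transform
  `h⁻¹(y) = ∫₀ʸ λ(t) dt` (so `Y = h(Z)` when `Θ ≡ 1`). The implemented
  families (Pareto-, Weibull-, lognormal-, loglogistic-, Gompertz-type
  plus the constant) are exactly the standard parametric transforms whose
  scalar `p = 1` cases reduce to the distributions they are named after.
  `h⁻¹` must be finite on `(0, ∞)` and increase to infinity; every family
  satisfies this on its stated parameter domain (lognormal needs `γ > 1`).
* `Θ` is a positive random scaling, the matrix analogue of a frailty.
  Distributionally `Y = h(Z/Θ)`, which is also how the simulator works.

Survival and density are matrix-analytic:

```
S(y) = π L_Θ(−h⁻¹(y) T) e          f(y) = −λ(y) π L'_Θ(−h⁻¹(y) T) t
```

where `L_Θ` is the Laplace transform of `Θ` evaluated at a matrix argument
via functional calculus. With covariates, `h⁻¹(y)` is multiplied by
`exp(βx)` (proportional intensities). No intercept is allowed in `β` and
the gamma scaling is fixed at rate 1: both constants are unidentifiable
against the scale of `T`.

Scaling families and their transforms:

| family | parameters (defaults/domains) | `L(u)` |
|---|---|---|
| degenerate | `k > 0` | `e^{−ku}` |
| gamma | shape `α > 0`, rate fixed 1 | `(1+u)^{−α}`, `u ≥ −1` |
| positive stable | `α ∈ (0,1]` | `exp(−u^α)` |
| inverse stable (`Θ = S_α^{−α}`) | `α ∈ (0,1]` | Mittag-Leffler `E_α(−u)` |
| inverse Gaussian | variance `σ² > 0`, unit mean | `exp((1−√(1+2σ²u))/σ²)` |
| PVF | `η > 0`, `γ ∈ (0,1]`, unit mean | `exp(c(1−(1+u/m)^γ))` |
| compound Poisson–gamma | `ρ, α > 0` | `exp(−ρ(1−(1+u)^{−α}))` |
| discrete | finite support/weights | mixture of exponentials |

The compound Poisson–gamma family is defective: `L(u) → e^{−ρ}` as
`u → ∞`, i.e. a cure fraction `e^{−ρ}` never experiences the event.
Discrete scalings must have finite support; truncating an infinite
support is the caller's responsibility.

The matrix Mittag-Leffler (fractional PH) law is the corner case where the
transform and the mixing law share one parameter: `h(x) = x^{1/α}` and
`Θ = S_α^{−α}`. `matrix_mittag_leffler(π, T, α)` assembles it from the
generic parts.

## Matrix functional calculus

`g(A)` is mathematically the Cauchy-integral functional calculus; numerically
it is evaluated by eigendecomposition when the eigenvector condition number
is below `1e8` and eigenvalues are separated, and by scipy's Schur–Parlett
`funm` otherwise (Parlett blocking handles clustered eigenvalues).
Fractional powers use the principal branch and raise on spectra touching
the closed negative real axis — `−T` of a valid representation always
qualifies. Survival/density evaluation uses the cached eigendecomposition
of `T` directly when well conditioned (one `exp` per eigenvalue per point)
and falls back to per-point matrix functions otherwise. Survival values
below `1e−300` are reported as exact zeros and flagged on the model
(`underflow`); hazards there are `inf` with a warning.

## Stable laws

Sampling uses the Chambers–Mallows–Stuck construction specialised to the
totally positively skewed case with `L(u) = exp(−u^α)`. Densities (both
`S_α` and the Mittag-Leffler mixing law `S_α^{−α}`) use Kanter's form of
the Zolotarev integral, evaluated with a fixed 96-node Gauss–Legendre rule
in the angle and everything else in log space (the integrand's prefactor
and exponent can separately overflow long before the product matters).
The `α = 1/2` Lévy closed form and the scalar Mittag-Leffler series serve
as test oracles; agreement is at the `1e−6`–`1e−8` level. The inverse
stable family's Laplace transform has no elementary form; it is computed
by quadrature of `E[e^{−uΘ}]` against the density on a 500-point
log-spaced grid with normalized weights, which reproduces reference values
to about `1e−9` (checked against a 6000-point grid and the Mittag-Leffler
series). `α = 1` degenerates to `Θ ≡ 1` and is handled exactly.

Laplace-transform derivatives up to order 4 (enough for 4-variate shared
densities) come from the closed falling-factorial form for the gamma
family and from the derivative recurrence for `exp(g)` families
(equivalent to Faà di Bruno/Bell polynomials) for stable, inverse
Gaussian, PVF and compound Poisson–gamma; matrix arguments reuse the same
scalar functions through the functional calculus, so no numerical matrix
differentiation occurs anywhere.

## Multivariate constructions

**Shared scaling.** Conditionally independent margins with one common
`Θ` give

```
S(y) = (π₁⊗…⊗π_d) L_Θ(−(T₁h₁⁻¹(y₁) ⊕ … ⊕ T_d h_d⁻¹(y_d))) e
f(y) = (Π λᵢ(yᵢ)) (−1)^d (π₁⊗…⊗π_d) L_Θ^{(d)}(…) (t₁⊗…⊗t_d)
```

evaluated through the product of marginal spectra (the Kronecker sum's
eigenvalues are sums), so the cost grows with `Π pᵢ`; joint densities are
limited to `d ≤ 4` by the implemented derivative orders, and survival to
Kronecker dimensions of order `10⁴`. Setting `y_j = 0` for `j ≠ i`
reduces the joint survival to margin `i` exactly (a matrix identity, and
a regression test). For `p = 1` margins the survival copula is
Archimedean with generator `L_Θ^{-1}`.

**Upper tail dependence.** For `d = 2` and `1/Θ` regularly varying with
index `α` (gamma scaling: `α` = shape),
`λ_U = Γ(α+1)(π₁⊗π₂)(−(T̃₁⊕T̃₂))^{−α} e` with
`T̃ᵢ = Tᵢ·E(Zᵢ^α)^{1/α}` and `E(Z^α) = Γ(α+1) π(−T)^{−α} e`. The
companion *empirical* estimator is the conditional exceedance frequency at
empirical marginal quantiles (default level 0.95) — a diagnostic, not an
estimator of the limit, and deliberately not asserted against any
published empirical number since such estimators are threshold-dependent.

**Correlated scaling** (bivariate): `Θᵢ = (W₀ + Gᵢ)/ηᵢ` with independent
`W₀ ~ Gamma(κ₀, 1)`, `Gᵢ ~ Gamma(κᵢ, 1)`, and by default the mean-one
normalization `ηᵢ = κ₀ + κᵢ`, under which
`Corr(Θ₁, Θ₂) = κ₀/√(η₁η₂)`. The joint survival is the product of three
commuting matrix powers (a runtime check asserts commutation before
multiplying); the density is the mixed second derivative, expanded in the
shared eigenbasis. `κ₀ → 0` factorizes into independent gamma-scaled
margins; `κ₁ = κ₂ = 0` degenerates to shared scaling — both limits are
regression tests.

## Estimation

All fits are generalized EM algorithms on the complete data
(hidden path, scaling variable):

1. **E-step.** Conditional on `(y, θ)` the path statistics — initial-state
   counts `B_k`, occupation times `Z_k`, transition counts `N_kl`, exits
   `N_k` — have the classical phase-type conditional expectations at the
   rescaled point `z = θ·h⁻¹(y)e^{βx}`, computed in closed form from the
   eigendecomposition (the convolution integrals
   `∫₀ᶻ e^{λᵢs}e^{λⱼ(z−s)}ds` have explicit two-point formulas, with the
   confluent `z e^{λz}` limit for near-equal eigenvalues). These are mixed
   over the posterior `f(θ|y) ∝ f_Θ(θ)·lik(θ;y)` by Gauss–Legendre
   quadrature on a log-θ axis (48 nodes by default). A fixed global node
   set cannot track posteriors that concentrate at `θ ~ 1/y` for extreme
   observations, so the quadrature interval is located per observation
   from a coarse scan that unions a scaling-family support grid with a
   likelihood-informed grid. Discrete scalings use exact finite sums;
   degenerate scaling uses the single atom.
2. **M-step.** `π̂_k = mean(B_k)`; `t̂_kl = ΣN_kl / ΣZ_k` on the rescaled
   time axis (states with vanishing expected occupation keep their current
   rates). The scaling parameter maximizes the expected scaling
   log-density (bounded 1-D optimization) for gamma, inverse Gaussian and
   degenerate families; for the positive stable family — whose density is
   itself an integral — it instead takes a guarded profile step on the
   observed likelihood within a moving local window. Both variants keep
   the observed likelihood non-decreasing.
3. **Profile step.** Intensity parameters `η` (log-parameterized) and
   regression coefficients `β` take a few Nelder–Mead steps
   (`inner_steps`, default 5) on the observed log-likelihood per outer
   iteration — full inner convergence is unnecessary for monotonicity.
   The Weibull shape is initialized from the log-scale spread of the data
   (`η₀ ≈ (π/√6)/sd(log y)`).

Right-censored records (univariate fits) contribute survival factors: the
censored conditional statistics add the expected future occupation
`(−T)^{−1}` from the state distribution at the censoring time, and the
status column follows the 1 = event, 0 = censored convention.

The matrix Mittag-Leffler fit is special because `α` appears in both the
transform and the mixing law: `(π, T)` take the scaled-PH E/M step on
`y^α` with inverse-stable mixing at the current `α`, then `α` is updated
by a guarded profile search over `(0, 1]` (moving window of width 0.12).
A fitted `α` above 0.995 is reported as a boundary (plain PH) solution.

Monotonicity policy: each stage is individually non-decreasing up to
quadrature error; a candidate `(π, T)` update that loses likelihood
(which can happen when the scaling is nearly degenerate and the posterior
nearly a point mass) is dropped for that iteration rather than accepted.
The recorded trace is non-decreasing to `1e−7`, asserted in the test
suite on every fit. Convergence is declared at relative log-likelihood
change below `tol` (default `1e−8`) or `max_iter`. EM reaches local
optima; fits run `restarts` independent initializations (default 3) and
return the best, with all restart scores reported. Initialization draws a
Dirichlet `π` and uniform rates (general or Coxian zero pattern), rescaled
so the PH mean matches the sample median scale.

The shared-scaling fit mixes per-margin statistics over the single joint
posterior of `Θ`. The correlated-gamma fit integrates over the three
independent components `(w₀, g₁, g₂)` — given `w₀` the margins decouple,
so the triple integral is evaluated as nested 1-D Gauss–Legendre rules on
the gamma supports (28 nodes per axis by default); the shape parameters
`(κ₀, κ₁, κ₂)` are updated by a guarded profile step on the closed-form
joint likelihood (their expected complete log-density has no closed form).

## Synthetic-data scenarios

`make_fixture` provides five seeded scenarios whose parameters are the
package's reference values:

* `mml_4phase` — 4-phase matrix Mittag-Leffler, `π = (0.2, 0.8, 0, 0)`,
  a fixed sparse `T` (exit vector `(0, 0, 0.5, 4)`), `α = 0.8`; default
  `n = 1000`.
* `matrix_weibull_3phase` — 3-phase matrix-Weibull (degenerate scaling,
  Weibull shape 2); default `n = 5000`. Used to test approximation of a
  *given* law by a stable-scaling SIPH fit, whose tail exponent is the
  product `αη`.
* `bivariate_gamma` — the 3×2-phase shared-gamma model (`α = 1.5`,
  `λ_U = 0.2765`); default `n = 2500`.
* `pareto_scalar`, `clayton_scalar` — scalar reductions with closed-form
  survival `(1+y)^{−α}` and Clayton copula (`λ_U = 2^{−α}`).

These generators emulate i.i.d. fully observed sampling from the exact
model; they do not emulate covariate heterogeneity, censoring mechanisms,
ties/rounding, or model misspecification, so passing tests demonstrate
correctness of the algorithms under the model, not robustness on real
data. Test problem sizes are the package's own choices: replicated
recovery experiments use n = 1000–5000 with 5–20 replicates, and the
correlated-scaling fits use a few hundred observations with one or two
restarts, which keeps each experiment's Monte-Carlo error comparable to
the tolerance it is tested against.

## Numerical defaults and degenerate inputs

* Eigen-route condition threshold `1e8`; eigenvalue clustering tolerance
  `1e−9·scale` switches convolution integrals to the confluent formula.
* Posterior quadrature: 48 log-axis Gauss–Legendre nodes per observation
  (coarse scan 240 + 160 points), integrand floor `e^{−38}` relative to
  the per-record peak.
* A posterior normalizer that is not finite raises with the offending
  record indices rather than silently dropping records.
* `PHRepresentation` validates sign patterns, row sums and the spectrum
  (absorption almost sure); `validate=False` is available for internal
  rescalings that preserve validity by construction.
* Sampling simulates the embedded jump chain with exponential holding
  times — exact, vectorized across paths, and bit-reproducible for a
  given seed.

## Known limitations

* General PVF densities/samplers are not implemented (the family is used
  through its Laplace transform; its named special cases have their own
  families). `tail_class` is a lookup of qualitative classes; the
  asymptotic constants are never estimated.
* Joint scaling beyond the correlated gamma (and beyond `d = 2`) is out
  of scope, as are reward- and copula-based multivariate PH constructions,
  left/interval censoring, time-varying covariates, and covariates on the
  scaling parameters.
* Likelihoods of heavy-tailed fits can have many local optima; restart
  counts are the user's main control. Fitted `(π, T)` are identified only
  up to state relabelling.
* Kronecker dimensions grow multiplicatively in `d`; the correlated-gamma
  E-step cost grows with the cube of the node count, which is why
  correlated fits are practical mainly for the bivariate case.
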