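# siphtool — scaled inhomogeneous phase-type survival models

Phase-type (PH) distributions — absorption times of finite-state Markov
jump processes — are flexible, interpretable survival models, but they are
always light-tailed. `siphtool` implements the *scaled inhomogeneous
phase-type* (SIPH) class, which removes that limitation by modulating the
chain's intensity with two extra ingredients:

* a deterministic **time transform**: the generator is `λ(t) T`, so the
  absorption time is `h(Z)` with `Z ~ PH(π, T)` and `h⁻¹(y) = ∫₀ʸ λ`;
* a random **scaling** `Θ` (the matrix analogue of a frailty): conditional
  on `Θ = θ` the intensity is `θ λ(t)`.

Every functional stays matrix-analytic through the Laplace transform of
`Θ` applied to a matrix argument:

```
S(y) = π L_Θ(−h⁻¹(y) T) e,          f(y) = −λ(y) π L'_Θ(−h⁻¹(y) T) t,
```

with `t = −T e` the exit-rate vector. Choosing the scaling law (gamma,
positive stable, inverse Gaussian, PVF, compound Poisson–gamma, finite
discrete) and the intensity family (Pareto-, Weibull-, lognormal-,
loglogistic-, Gompertz-type) produces any desired tail behaviour — from
slowly varying to Gumbel — while keeping the hidden-Markov interpretation.
Matrix Mittag-Leffler (fractional phase-type) laws are the special case
`h(x) = x^{1/α}`, `Θ = S_α^{−α}` for a positive stable `S_α`.

The package targets statisticians and actuaries modelling heavy-tailed
durations (insurance claims, lifetimes at old ages, legal-case durations)
who want a fit with an underlying-process interpretation. It provides:

* `matfun` — matrix functional calculus (`g(A)` for analytic `g`,
  fractional powers, Kronecker sums);
* `components` — PH representations, intensity families, scaling families
  with scalar- and matrix-argument Laplace transforms and derivatives;
* `univariate` — `SIPHModel`: survival/density/hazard, covariates via
  proportional intensities, exact simulation, qualitative tail
  classification;
* `multivariate` — shared-scaling models (one `Θ` for all margins, joint
  density via `d`-th Laplace derivatives of a Kronecker-sum argument) and
  correlated gamma scalings, plus the closed-form upper tail dependence
  `λ_U = Γ(α+1)(π₁⊗π₂)(−(T̃₁⊕T̃₂))^{−α} e`,
  `T̃ᵢ = Tᵢ E(Zᵢ^α)^{1/α}`;
* `estimation` — generalized EM maximum likelihood for all of the above
  (right-censoring and covariates in the univariate case), with monotone
  log-likelihood traces;
* `io` / a thin `siphtool` CLI — delimited-text observations, JSON model
  documents, named synthetic-data scenarios, fit reports.

## Worked example

Shared gamma scaling across two phase-type margins (`examples/shared_bivariate.py`):

```python
from siphtool import (make_fixture, shared_em_fit, tail_dependence_upper,
                      empirical_tail_dependence)

data, model = make_fixture("bivariate_gamma", n=2500, seed=5)
print(tail_dependence_upper(model))          # 0.2765
emp = empirical_tail_dependence(data.values, q=0.95)
res = shared_em_fit(data, p=(3, 2), intensity="constant", scaling="gamma",
                    max_iter=80, seed=0, restarts=1)
print(res.model.scaling.alpha, tail_dependence_upper(res.model))
```

Output on this seed:

```
theoretical upper tail dependence lambda_U = 0.2765
Clayton copula with the same alpha would give 0.3536
empirical exceedance estimate at q=0.95: 0.328 (biased toward the sub-asymptotic level)
EM: 80 iterations, loglik -11776.10
fitted gamma shape alpha = 1.4646 (truth 1.5)
tail dependence of the fitted model: 0.2856
```

Reading the numbers: the model's joint extremes are genuinely dependent
(`λ_U = 0.2765` — roughly a 28% chance one coordinate is extreme given the
other is), and this differs from the Clayton value `2^{−α} = 0.354` because
the margins have non-trivial phase structure. The EM fit recovers both the
gamma shape (1.46 vs 1.5) and the tail-dependence coefficient (0.286 vs
0.2765) from 2,500 observations, even though the hidden states themselves
are only identified up to relabelling.

The other scripts in `examples/` each exercise one capability: univariate
evaluation and tail classification, simulate-and-refit for Pareto-type
data, matrix Mittag-Leffler estimation, and correlated gamma scalings.

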