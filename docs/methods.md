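# Methods

## The modelling problem

Annual utilization counts (outpatient visits here) are non-negative
integers with three awkward features: a point mass at or near zero, heavy
right skew, and conditional variance far above the conditional mean. The
package treats the choice among nine count likelihoods as an empirical
question and provides the machinery to answer it: maximum-likelihood fits,
an in-sample battery, out-of-sample cross-validation, and effects for the
two-part winner.

## Families and parameterisations

All count parts use the log link, μᵢ = exp(xᵢ′β).

* **Poisson** — f(y|x) = e^{−μ} μ^y / y!.
* **NB2** — negative binomial with gamma heterogeneity of rate; shape
  r = 1/α, success probability r/(r + μ); V[y|x] = μ + αμ². α > 0 is a
  single free dispersion parameter, estimated on the log scale.
* **NB1** — same conditional mean, variance linear in the mean. The
  density is a negative binomial with shape μ/α and success probability
  1/(1 + α), which gives V[y|x] = μ(1 + α) exactly.
* **Hurdle families** — a logit zero part models Pr(y = 0 | z) directly
  (so a *larger* zero-part linear predictor means a *larger* probability of
  zero; the summary footer restates this to prevent sign confusion), and a
  zero-truncated Poisson/NB1/NB2 governs the positives:
  Pr(y = j | j > 0) ∝ f₂(j)/(1 − f₂(0)). The joint likelihood factorizes,
  so the two parts are maximized independently and the joint maximum is
  their sum — an identity the tests verify rather than assume.
* **Zero-inflated families (ZIP, ZINB2)** — a logit structural-zero
  probability q(z) mixes with the count density: zeros arise both
  structurally and from the count process,
  Pr(0) = q + (1 − q) f₂(0). By default the inflation part uses the same
  covariate set as the count part.
* **Latent-class NB2 (`lcnb2`)** — a C-component mixture
  Σ_c π_c f_NB2(y; μ_c, α_c) with unrestricted (β_c, α_c) per class and
  mixing weights on a multinomial-logit scale. C defaults to 2; larger C is
  accepted but not exercised by the test-suite.

Only the NB2 density is offered inside the mixture: linear-variance
mixture components and three-component fits are notoriously fragile, and
two NB2 classes already capture the "healthy vs ill" heterogeneity story
the mixture is used for.

## Estimation

Quasi-Newton (L-BFGS-B) on unconstrained transforms: log α for
dispersions, multinomial logits for mixing weights. Analytic gradients are
used throughout, including the zero-truncation and zero-inflation terms
(the truncation correction only needs d log f₂(0) in η and log α).
Design matrices are centered and scaled internally (intercept untouched);
the map back to the original basis is linear and exact, so reported
coefficients and covariances are unaffected by the conditioning trick.

Initialization: count parts start from a Poisson fit (positives only for
hurdle parts); zero parts from a logit fit of 1{y = 0}; zero-inflated fits
from the corresponding count fit plus an inflation intercept at half the
excess-zero fraction; mixture fits from seeded random perturbations of the
one-component NB2 fit.

The mixture is fitted by EM: posterior class probabilities in the E-step,
exact weight updates and warm-started weighted NB2 maximizations in the
M-step, which makes the log-likelihood trace non-decreasing by
construction (stored on the results object and asserted in tests). Each
random restart runs a short EM burst; the best burst is then polished by a
quasi-Newton step on the full mixture likelihood at machine-level function
tolerance — boundary optima, where one class dispersion heads to zero and
the class degenerates towards a Poisson, approach their supremum through
many tiny steps and need the tight tolerance.

Relative log-likelihood tolerance 1e-8, at most 500 iterations, 10 EM
restarts by default; all three are `FitSettings` fields. Convergence flags
are honest: a fit that stops on the iteration cap or fails the line search
is returned flagged, reported as non-converged, and excluded from
best-model declarations.

Standard errors invert the observed information (central-difference
Hessian of the analytic gradient in the working parameterisation), then
delta-transform to the natural scale (α from log α, mixing weights through
the softmax Jacobian). Hurdle parts are independent blocks. The number of
free parameters k is counted from the actual design matrices.

## Model selection battery

* **RESET** — refit the Poisson with powers {2, 3, 4} of its fitted
  values appended (standardized; collinear powers dropped with a warning
  and the degrees of freedom reduced) and LR-test the added terms against
  χ²(number of retained powers). Powers of the fitted *mean* are the
  default; powers of the linear predictor are available via
  `basis="linpred"`.
* **LR tests** — 2·ΔlnL over the recognised nested pairs
  (Poisson ⊂ {hurdle-Poisson, NB1, NB2, ZIP}; NB1 ⊂ HNB1; NB2 ⊂ HNB2;
  ZIP ⊂ ZINB2). A negative statistic beyond 1e-6 raises: a nesting model
  fitting worse than its restriction can only be a convergence failure.
* **Vuong** — V = m̄√N / s_m with mᵢ the difference in log predicted
  probability of the observed count, s_m the population (ddof = 0)
  standard deviation, no information-criterion correction; first model
  favored above +1.96, second below −1.96, inconclusive between.
  Comparisons involving a zero-inflated family are reported with an
  explicit caution note (the statistic's usual justification does not
  cover them); they are never silently suppressed.
* **AIC/BIC** — exact formulas, re-derived from each row's lnL and k in
  the report rather than cached. Best model = lowest AIC among converged
  fits, ties broken by BIC.
* **Per-count goodness of fit** — observed proportion vs mean predicted
  probability for counts 0..J (J = 20 default). RMSE and MAPE are computed
  over the J+1 count *cells* and expressed in percentage points — the
  reading under which "bias between predicted probabilities and observed
  proportions for each count" is well defined and the values land in the
  sub-percentage to low-percentage range for well-fitting models. A
  per-observation alternative (each observation contributing its own
  count-cell deviation) is available behind `per_observation=True`.

## Cross-validation

One uniform random partition into K folds (sizes differing by at most
one), shared by every model — fold membership is fixed for the whole
exercise. For each fold, each model is trained on the other K−1 folds and
scored by the *sum* of held-out log-likelihood terms on the validation
fold (differences against the baseline are unaffected by sum-vs-mean up to
a constant factor; sums are reported). Non-converged training fits yield a
missing fold entry with a warning rather than aborting the comparison, and
missing entries drop out of pairwise differences. NB2 is the conventional
baseline.

## Marginal effects and profiles

For hurdle fits the target is the unconditional mean
E[y|x] = (1 − π(z)) · μ(x) / (1 − f₂(0|x)). Binary covariates get the
sample-average discrete 0→1 change; continuous covariates the
sample-average central-difference derivative (step 1e-5 × the column
scale). Age and age-squared are deliberately treated as separate
regressors in the effects table; profile predictions, by contrast, keep
age² consistent with age, since a profile describes a person.

Uncertainty comes from a nonparametric pairs bootstrap (default B = 500):
each resample refits *both* parts and rebuilds the effect, preserving the
dependence between the separately estimated parts. Standard errors are
bootstrap standard deviations, p-values normal-approximation two-sided.
A bootstrap failure rate above 20% aborts with a diagnostic. B = 0 returns
point estimates with the uncertainty columns flagged NaN.

Profile probabilities evaluate the fitted pmf at counts 0–10 for six
age-sex groups (band midpoints 64.5, 74.5, 90 by default bands) crossed
with insurance status, with remaining continuous covariates at sample
means and binary/indicator covariates at their sample mode; the reported
counts deliberately do not sum to one (the tail lies beyond count 10).

## The synthetic generator

The generator emulates a cross-sectional household-survey sample of people
aged 60+ through *marginal* structure only: ten binary prevalences
(female 0.599, Kinh ethnicity 0.894, urban 0.262, single 0.405, insurance
0.549, subsidy 0.587, employed 0.424, smoking 0.323, NCD 0.356, disability
0.285), an eight-region categorical (reference Red River Delta; the
published shares sum to 0.999 from rounding and are renormalised to exactly
one), truncated-normal age 71.5 (7.98) on [60, 100] — 100 as an artifact
cap — and education 4.1 (3.6) on [0, 20], and normal log household size
1.25 (0.57) and log income 10.0 (0.88). Columns are drawn independently; a
`hook` callable is the opt-in dependence mechanism. Default n = 2426.

The default outcome truth is a hurdle-NB2 calibrated once against the
survey's descriptive statistics — zero intercept −1.72, count intercept
−0.69, dispersion α = 3.8, with moderate covariate effects in both parts —
giving mean ≈ 4.3 visits, variance roughly nine to ten times the mean,
≈ 8% zeros and ≈ 97% of mass on counts 0–20. What passing tests on this
generator shows is that the estimators and the selection machinery behave
correctly when the data-generating process is known; it does not show
anything about covariate dependence, survey design effects (stratification,
weights) or measurement error in real survey data, all of which are out of
scope.

## Numerical choices and edge cases

* Linear predictors are clipped at ±30 and log-dispersions at ±15 inside
  the optimizer only; user-facing density evaluations are unclipped.
* log(1 − e^x) uses the two-regime stable form; zero-inflated zero cells
  use log-sum-exp.
* Simulation of truncated counts uses exact inverse-cdf sampling on
  (f₂(0), 1], not rejection.
* Degenerate data fail fast: an all-zero outcome, or a hurdle fit without
  both zeros and positives, raises a dedicated error.
* The Vuong statistic is undefined (raises) when the two predictive
  distributions coincide; identical fits are the canonical case.
* An LR statistic below −1e-6 raises rather than being clamped silently.

## Problem sizes used by the test-suite and acceptance script

Simulation-backed checks run at the sizes a laptop handles comfortably:
parameter recovery at n = 5000 with 100 replicates per family (two EM
restarts for the mixture), selection consistency over 20 survey-scale
replicates (n = 2426), RESET size over 500 replicates at n = 300, the
grid-search oracle on n = 50 toys, and B = 100–200 bootstrap draws where
effects uncertainty is exercised. The acceptance script runs the full
nine-model study once at n = 2426.

## Known limitations

* Covariate independence in the generator is a deliberate simplification;
  real surveys have strong age–employment–insurance dependence.
* No survey weights or design-based variance; likelihoods are iid.
* Mixtures with C > 2 are accepted but untested; label switching is
  handled only at the comparison level (tests match classes up to
  permutation), not by an identifiability constraint inside the fitter.
* Robust (sandwich) covariances are not provided; standard errors are
  observed-information based, bootstrap for the effects table.
* The zero-inflated fits can sit on the q → 0 boundary when the data have
  no excess zeros; they then reproduce the count-only fit with inflated k,
  which is the expected behaviour, and the boundary makes their reported
  zero-part standard errors unreliable.
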