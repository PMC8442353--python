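# countfit

Maximum-likelihood count regression for skewed, overdispersed utilization
outcomes — the number of outpatient visits a person makes in a year, doctor
visits, hospital contacts — together with the model-selection battery needed
to decide *which* count model a given dataset actually supports.

Utilization counts typically concentrate on a few small values, carry a
point mass at zero and a long right tail, and have variance far above the
mean. `countfit` implements nine likelihoods spanning the standard modelling
choices, a three-step selection procedure (specification test, in-sample
battery, cross-validation), and unconditional marginal effects for the
two-part winner. It is aimed at health economists and epidemiologists who
want the whole comparison reproducible from one seed, including on synthetic
data when the underlying survey microdata cannot be redistributed.

## Models

All families share the log-link conditional mean μᵢ = exp(xᵢ′β).

| family | description |
|---|---|
| `poisson` | equidispersed baseline, V[y\|x] = μ |
| `nb1` | negative binomial, linear variance V = μ(1 + α) |
| `nb2` | negative binomial, quadratic variance V = μ + αμ² |
| `hurdle_poisson`, `hurdle_nb1`, `hurdle_nb2` | logit zero part Pr(y = 0 \| z) = Λ(z′γ) plus a zero-truncated count part f₂(y)/(1 − f₂(0)) on the positives |
| `zip`, `zinb2` | zero inflation: Pr(y = 0) = q + (1 − q) f₂(0), with a logit structural-zero part q(z) |
| `lcnb2` | C-component finite mixture of NB2 densities, Σ_c π_c f_c(y), fitted by EM with random restarts |

Hurdle likelihoods factorize, so the two parts are maximized separately and
their log-likelihoods added. The hurdle unconditional mean combines both
parts, E[y|x] = (1 − π(z)) · μ / (1 − f₂(0|x)), and is the quantity the
marginal-effects table differentiates.

The selection battery covers: Ramsey's RESET for the Poisson mean
(powers of fitted values, jointly LR-tested), likelihood-ratio tests for
nested pairs, the Vuong statistic V = m̄√N / s_m for non-nested pairs
(mᵢ the difference in log predicted probability of the observed count,
±1.96 decision rule), AIC = −2lnL + 2k and BIC = −2lnL + ln(N)k, and
per-count goodness of fit for counts 0–20 (observed proportions vs mean
predicted probabilities, summarised as RMSE/MAPE in percentage points).
K-fold cross-validation compares held-out log-likelihood per fold against
an NB2 baseline on one shared fold assignment.

## Worked example

Simulate a survey-scale dataset (n = 2426) from the calibrated hurdle-NB2
truth, fit three contenders, and run the battery:

```python
import warnings
from countfit import (CountModel, CovariateConfig, ModelSpec, cv_compare,
                      default_dgp, generate_covariates, kfold_split,
                      make_dataset, selection_report, simulate_counts)

cov = generate_covariates(CovariateConfig(n=2426, seed=7))
y = simulate_counts(default_dgp("hurdle_nb2", seed=8), cov)
data = make_dataset(cov, y)

fits = {m: CountModel(data, m).fit() for m in ("poisson", "nb2", "hurdle_nb2")}
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = selection_report(fits, data, J=20)
print(report.table[["k", "llf", "aic", "bic", "rmse", "mape"]].round(3))
print("best:", report.best)

folds = kfold_split(data.n, 10, seed=9)
cv = cv_compare([ModelSpec(m) for m in ("nb2", "hurdle_nb2")], data, folds)
print("fold wins:", cv.wins().to_dict())
```

prints

```
             k       llf        aic        bic   rmse   mape
model
poisson     23 -9285.010  18616.021  18749.283  5.539  3.147
nb2         24 -6217.712  12483.424  12622.480  3.610  1.663
hurdle_nb2  47 -5954.213  12002.427  12274.745  0.318  0.226
best: hurdle_nb2
fold wins: {'hurdle_nb2': 10, 'nb2': 0}
```

Reading it: the Poisson is overwhelmed by the overdispersion (its AIC is
6600 points worse than NB2's); allowing a separate zero process buys the
hurdle-NB2 another ~480 AIC points and an order of magnitude better
per-count fit (RMSE 0.32 vs 3.6 percentage points), and it wins all ten
cross-validation folds — exactly the behaviour expected when the data truly
come from a two-part process. `fits["hurdle_nb2"].summary()` shows the
coefficient table of both parts; `average_marginal_effects` turns it into
visits-per-year effects with bootstrap standard errors.

The same pipeline runs from the shell:

```sh
countfit simulate --family hurdle_nb2 --n 2426 --seed 7 --out visits.csv
countfit select --data visits.csv --models poisson,nb2,hurdle_nb2
countfit cv --data visits.csv --models nb1,nb2,hurdle_nb1,hurdle_nb2
countfit effects --data visits.csv --family hurdle_nb2
countfit run --config study.yaml --outdir out/   # everything, from YAML
```

## Layout

- `countfit.families` — log-pmf kernels (Poisson, NB1, NB2, truncation, logit zero part)
- `countfit.model` — `CountModel` / `CountResults`, ML fitting for all nine families
- `countfit.selection` — RESET, LR, Vuong, AIC/BIC, per-count goodness of fit
- `countfit.crossval` — fold assignment and held-out log-likelihood comparison
- `countfit.effects` — unconditional marginal effects, profile probabilities
- `countfit.simulate` — covariate generator and known-truth outcome simulation
- `countfit.pipeline` / `countfit.cli` — one-config orchestration and the CLI

See `docs/methods.md` for modelling assumptions, parameterisations and
numerical choices.
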