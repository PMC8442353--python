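"""Likelihood construction, ML fitting, and prediction for all families."""

import numpy as np
import pandas as pd
import pytest

from countfit import (
    CountDataset,
    CountModel,
    DegenerateDataError,
    FitSettings,
    ModelSpec,
    fit_model,
    model_loglik,
)
from countfit.model import CountResults

from conftest import dgp_for, toy_dataset


def intercept_only(y):
    y = np.asarray(y)
    return CountDataset(y, np.ones((y.size, 1)), ["const"])


class TestLoglikIdentities:
    def test_hurdle_loglik_factorizes(self, quick_settings):
        ds = toy_dataset("hurdle_nb2", 400, 1, beta={"const": 1.0, "x1": 0.4},
                         gamma={"const": -0.5, "x1": 0.3}, alpha=1.0)
        fit = CountModel(ds, "hurdle_nb2", settings=quick_settings).fit()
        # joint maximized lnL is the sum of the two separately maximized parts
        assert fit.llf == pytest.approx(
            fit.extra["llf_zero"] + fit.extra["llf_positive"], abs=1e-6
        )
        # and equals the observation-level likelihood at the fitted parameters
        assert fit.llf == pytest.approx(fit.loglike(), abs=1e-6)

    def test_zip_at_zero_inflation_equals_poisson(self):
        ds = toy_dataset("poisson", 200, 2, beta={"const": 0.8, "x1": 0.2})
        beta = np.array([0.8, 0.2, -0.1])
        lp = model_loglik("poisson", {"beta": beta}, ds)
        lz = model_loglik(
            "zip", {"beta": beta, "gamma": np.array([-40.0, 0.0, 0.0])}, ds
        )
        assert lz == pytest.approx(lp, abs=1e-8)

    def test_lcnb2_single_class_equals_nb2(self):
        ds = toy_dataset("nb2", 200, 3, beta={"const": 0.8, "x1": 0.2}, alpha=1.0)
        beta = np.array([0.8, 0.2, -0.1])
        l2 = model_loglik("nb2", {"beta": beta, "alpha": 0.7}, ds)
        lc = model_loglik(
            "lcnb2", {"pi": np.array([1.0]), "class_beta": [beta], "class_alpha": [0.7]}, ds
        )
        assert lc == pytest.approx(l2, abs=1e-10)

    def test_nb2_approaches_poisson_as_dispersion_vanishes(self):
        ds = toy_dataset("poisson", 300, 4, beta={"const": 1.0})
        beta = np.array([1.0, 0.2, 0.1])
        lp = model_loglik("poisson", {"beta": beta}, ds)
        gaps = [
            abs(model_loglik("nb2", {"beta": beta, "alpha": a}, ds) - lp)
            for a in (1e-2, 1e-4, 1e-6)
        ]
        assert gaps[0] > gaps[1] > gaps[2]
        assert gaps[2] < 1e-3


class TestFitting:
    def test_intercept_only_poisson_recovers_sample_mean(self):
        fit = CountModel(intercept_only([0, 1, 2, 3]), "poisson").fit()
        assert np.exp(fit.params["beta"][0]) == pytest.approx(1.5, abs=1e-6)

    def test_intercept_only_hurdle_zero_part_is_zero_fraction(self):
        y = np.array([0, 0, 0, 1, 2, 5, 1, 0, 2, 4])
        fit = CountModel(intercept_only(y), "hurdle_poisson").fit()
        p0 = fit.predict_prob(0)[0]
        assert p0 == pytest.approx(np.mean(y == 0), abs=1e-6)

    def test_em_loglik_never_decreases(self, quick_settings):
        ds = toy_dataset("lcnb2", 500, 5, classes=[
            (0.6, {"const": 0.3, "x1": 0.4}, 0.5), (0.4, {"const": 1.8, "x1": -0.3}, 1.0)
        ])
        fit = CountModel(ds, "lcnb2", settings=quick_settings).fit()
        assert np.all(np.diff(fit.history) >= -1e-7)
        assert fit.params["pi"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_all_zero_outcome_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            CountModel(intercept_only([0, 0, 0, 0]), "poisson").fit()

    def test_hurdle_needs_both_zeros_and_positives(self):
        with pytest.raises(DegenerateDataError):
            CountModel(intercept_only([1, 2, 3]), "hurdle_nb2").fit()

    def test_fit_model_spec_roundtrip(self):
        ds = toy_dataset("nb2", 300, 6, beta={"const": 1.0, "x1": 0.4}, alpha=1.0)
        fit = fit_model(ModelSpec("nb2"), ds)
        assert fit.converged
        assert fit.k == 4  # intercept + 2 covariates + dispersion

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            CountModel(intercept_only([0, 1]), "weibull")


class TestAgainstStatsmodels:
    """Independent oracle: identical likelihoods imply identical optima."""

    def test_poisson_estimates_and_errors(self):
        import statsmodels.api as sm

        ds = toy_dataset("poisson", 600, 7, beta={"const": 1.0, "x1": 0.4, "x2": 0.3})
        fit = CountModel(ds, "poisson").fit()
        ref = sm.Poisson(ds.y, ds.X).fit(disp=0)
        np.testing.assert_allclose(fit.params["beta"], ref.params, atol=1e-5)
        np.testing.assert_allclose(fit.llf, ref.llf, atol=1e-6)
        np.testing.assert_allclose(fit.bse.to_numpy(), ref.bse, rtol=1e-4)

    def test_nb2_loglik_matches(self):
        import statsmodels.api as sm

        ds = toy_dataset("nb2", 600, 8, beta={"const": 1.0, "x1": 0.4}, alpha=0.8)
        fit = CountModel(ds, "nb2").fit()
        ref = sm.NegativeBinomial(ds.y, ds.X).fit(disp=0)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-4)
        assert fit.params["alpha"] == pytest.approx(ref.params[-1], rel=1e-3)

    def test_zip_loglik_matches(self):
        from statsmodels.discrete.count_model import ZeroInflatedPoisson

        ds = toy_dataset("zip", 600, 9, beta={"const": 1.0, "x1": 0.4},
                         gamma={"const": -1.0, "x1": 0.5})
        fit = CountModel(ds, "zip").fit()
        ref = ZeroInflatedPoisson(ds.y, ds.X, exog_infl=ds.Z).fit(disp=0, maxiter=500)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-4)


ALL_FAMILIES = [
    "poisson", "nb1", "nb2", "hurdle_poisson", "hurdle_nb1", "hurdle_nb2",
    "zip", "zinb2", "lcnb2",
]


@pytest.fixture(scope="module")
def fits_by_family():
    settings = FitSettings(restarts=3, seed=2)
    out = {}
    for family in ALL_FAMILIES:
        ds = toy_dataset(family, 500, 11, **_kwargs(family))
        out[family] = CountModel(ds, family, settings=settings).fit()
    return out


def _kwargs(family):
    d = dgp_for(family)
    out = {}
    if d.beta is not None:
        out["beta"] = d.beta
    if d.gamma is not None:
        out["gamma"] = d.gamma
    if d.alpha is not None:
        out["alpha"] = d.alpha
    if d.classes is not None:
        out["classes"] = d.classes
    return out


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_predicted_probabilities_normalize(fits_by_family, family):
    """Summing predict_prob over counts reaches one for every row and family."""
    fit = fits_by_family[family]
    total = np.zeros(fit.nobs)
    for j in range(1500):
        total += fit.predict_prob(j)
        if total.min() > 1 - 1e-8:
            break
    np.testing.assert_allclose(total, 1.0, atol=1e-6)


@pytest.mark.parametrize("family", ALL_FAMILIES)
def test_predicted_mean_consistent_with_pmf(fits_by_family, family):
    """predict_mean equals sum_j j * P(j) within the truncation tolerance."""
    fit = fits_by_family[family]
    total = np.zeros(fit.nobs)
    for j in range(1, 4000):
        total += j * fit.predict_prob(j)
    np.testing.assert_allclose(fit.predict_mean(), total, atol=1e-4, rtol=1e-6)


def test_hurdle_zero_probability_is_zero_part_exactly(fits_by_family):
    fit = fits_by_family["hurdle_nb2"]
    ds = fit.model.dataset
    from countfit import zero_prob_logit

    np.testing.assert_allclose(
        fit.predict_prob(0), zero_prob_logit(ds.Z, fit.params["gamma"]), atol=1e-12
    )


def test_zip_zero_probability_formula(fits_by_family):
    fit = fits_by_family["zip"]
    ds = fit.model.dataset
    from countfit import zero_prob_logit

    q = zero_prob_logit(ds.Z, fit.params["gamma"])
    mu = np.exp(ds.X @ fit.params["beta"])
    np.testing.assert_allclose(fit.predict_prob(0), q + (1 - q) * np.exp(-mu), atol=1e-10)


def test_summary_renders(fits_by_family):
    text = fits_by_family["hurdle_nb2"].summary()
    assert "zero:const" in text and "alpha" in text and "Pr(y = 0)" in text
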