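"""The in-sample battery: RESET, LR, Vuong, information criteria, GOF."""

import warnings

import numpy as np
import pandas as pd
import pytest

from countfit import (
    CountDataset,
    CountModel,
    FitSettings,
    TrueDGP,
    gof_rmse_mape,
    information_criteria,
    lr_test,
    make_dataset,
    prob_fit_table,
    reset_test,
    selection_report,
    vuong_test,
)
from countfit.model import CountResults
from countfit.selection import VUONG_CRITICAL, ProbFitTable, chi2_critical

from conftest import toy_covariates, toy_dataset


class _FakeFit:
    """Stands in for a CountResults in pure-arithmetic tests (synthetic)."""

    def __init__(self, llf, k, family="m", nobs=100, loglikeobs_values=None):
        self.llf = llf
        self.k = k
        self.family = family
        self.nobs = nobs
        self.converged = True
        self._obs = loglikeobs_values

    def loglikeobs(self, dataset=None):
        return np.asarray(self._obs)


class TestInformationCriteria:
    def test_zero_loglik_zero_parameters(self):
        assert information_criteria(_FakeFit(0.0, 0, nobs=1)) == (0.0, 0.0)

    def test_formulas(self):
        aic, bic = information_criteria(_FakeFit(-100.0, 5, nobs=50))
        assert aic == pytest.approx(210.0)
        assert bic == pytest.approx(200.0 + np.log(50) * 5)


class TestLRTest:
    def test_identical_fits_give_zero(self):
        t = lr_test(_FakeFit(-10.0, 3), _FakeFit(-10.0, 5))
        assert t.statistic == 0.0

    def test_negative_statistic_flags_convergence_failure(self):
        with pytest.raises(ValueError, match="convergence"):
            lr_test(_FakeFit(-10.0, 3), _FakeFit(-11.0, 5))

    def test_statistic_is_twice_loglik_gap(self):
        t = lr_test(_FakeFit(-200.0, 3), _FakeFit(-150.0, 6))
        assert t.statistic == pytest.approx(100.0)
        assert t.df == 3


class TestVuong:
    def _pair(self, seed=0, n=20):
        """Two prespecified Poisson parameter vectors on a small fixture."""
        rng = np.random.default_rng(seed)
        cov = toy_covariates(n, seed)
        y = simulated = rng.poisson(2.0, size=n)
        ds = make_dataset(cov, y)
        from countfit import model_loglik
        from countfit.model import loglikeobs

        b1 = np.array([0.6, 0.3, 0.1])
        b2 = np.array([0.8, -0.2, 0.2])
        f1 = _FakeFit(0, 0, "A", n, loglikeobs(("poisson"), {"beta": b1}, ds))
        f2 = _FakeFit(0, 0, "B", n, loglikeobs(("poisson"), {"beta": b2}, ds))
        return ds, f1, f2, b1, b2

    def test_antisymmetry_exact(self):
        ds, f1, f2, *_ = self._pair()
        assert vuong_test(f1, f2).statistic == -vuong_test(f2, f1).statistic

    def test_identical_models_undefined(self):
        ds, f1, _, *_ = self._pair()
        with pytest.raises(ValueError, match="undefined"):
            vuong_test(f1, f1)

    def test_matches_straight_line_oracle(self):
        """Hand-rolled mean/sd computation of the normal statistic."""
        ds, f1, f2, b1, b2 = self._pair(seed=4)
        # oracle: plain loops over the definition, scipy pmf for the density
        from scipy.stats import poisson as pois

        m = []
        for i in range(ds.n):
            mu1 = np.exp(b1 @ ds.X[i])
            mu2 = np.exp(b2 @ ds.X[i])
            m.append(np.log(pois.pmf(ds.y[i], mu1)) - np.log(pois.pmf(ds.y[i], mu2)))
        m = np.array(m)
        vbar = m.mean() * np.sqrt(ds.n) / m.std(ddof=0)
        assert vuong_test(f1, f2).statistic == pytest.approx(vbar, abs=1e-10)

    def test_zero_inflated_pairs_carry_warning(self):
        ds = toy_dataset("zip", 300, 5, beta={"const": 1.0}, gamma={"const": -1.0})
        fz = CountModel(ds, "zip").fit()
        fn = CountModel(ds, "nb2").fit()
        with pytest.warns(UserWarning, match="zero-inflated"):
            t = vuong_test(fz, fn)
        assert t.note


class TestCriticalValues:
    def test_one_percent_chi_square_values(self):
        assert round(chi2_critical(34, 0.01), 1) == 56.1
        assert round(chi2_critical(1, 0.01), 1) == 6.6

    def test_vuong_threshold_is_two_sided_five_percent_normal(self):
        assert round(VUONG_CRITICAL, 2) == 1.96


class TestReset:
    def test_empty_powers_rejected(self):
        ds = toy_dataset("poisson", 50, 1, beta={"const": 1.0})
        with pytest.raises(ValueError):
            reset_test(ds, powers=())

    def test_size_close_to_nominal_under_correct_specification(self):
        """Rejection rate at the 5% level stays near 5% when the mean is right."""
        reps, n = 500, 300
        rejections = 0
        for rep in range(reps):
            cov = toy_covariates(n, 9000 + rep)
            y = TrueDGP("poisson", beta={"const": 0.8, "x1": 0.4, "x2": 0.3},
                        seed=500 + rep)
            ds = make_dataset(cov, __import__("countfit").simulate_counts(y, cov))
            t = reset_test(ds)
            rejections += t.p_value < 0.05
        rate = rejections / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_power_against_omitted_quadratic(self):
        """An omitted squared covariate is detected more often than the size."""
        reps, n = 60, 300
        rejections = 0
        rng_counts = __import__("countfit").simulate_counts
        for rep in range(reps):
            rng = np.random.default_rng(7000 + rep)
            cov = pd.DataFrame({"x1": rng.normal(size=n)})
            mu = np.exp(0.5 + 0.3 * cov.x1 + 0.35 * cov.x1**2)
            y = rng.poisson(mu)
            ds = make_dataset(cov, y)  # x1^2 deliberately omitted
            rejections += reset_test(ds).p_value < 0.05
        assert rejections / reps > 0.3


class TestProbFitTable:
    def _fit(self, n=300, seed=2):
        ds = toy_dataset("nb2", n, seed, beta={"const": 1.0, "x1": 0.4}, alpha=1.0)
        return CountModel(ds, "nb2").fit(), ds

    def test_saturated_model_matches_observed(self):
        """A model reproducing the empirical pmf predicts the observed column."""
        y = np.array([0, 0, 1, 1, 2, 3])
        ds = CountDataset(y, np.ones((6, 1)), ["const"])
        emp = np.bincount(y, minlength=4) / y.size

        class Saturated:
            family = "saturated"

            def predict_prob(self, j, dataset=None):
                p = emp[j] if j < len(emp) else 0.0
                return np.full(y.size, p)

        table = prob_fit_table({"sat": Saturated()}, ds, J=3)
        np.testing.assert_allclose(table.predicted["sat"], table.observed, atol=1e-12)

    def test_single_cell_table(self):
        fit, ds = self._fit()
        table = prob_fit_table({"nb2": fit}, ds, J=0)
        assert len(table.counts) == 1

    def test_intercept_only_poisson_zero_cell(self):
        y = np.array([0, 0, 1, 3])
        ds = CountDataset(y, np.ones((4, 1)), ["const"])
        fit = CountModel(ds, "poisson").fit()
        table = prob_fit_table({"poisson": fit}, ds, J=2)
        assert table.predicted["poisson"][0] == pytest.approx(np.exp(-1.0), abs=1e-6)
        assert table.observed[0] == pytest.approx(0.5)

    def test_observed_proportions_sum_to_at_most_one(self):
        fit, ds = self._fit()
        table = prob_fit_table({"nb2": fit}, ds, J=20)
        assert table.observed.sum() <= 1.0 + 1e-12
        assert table.observed.sum() + table.observed_tail == pytest.approx(1.0)


class TestGof:
    def _table(self, observed, predicted):
        counts = np.arange(len(observed))
        return ProbFitTable(
            counts=counts,
            observed=pd.Series(observed, index=counts),
            predicted=pd.DataFrame({"m": predicted}, index=counts),
            observed_tail=0.0,
            predicted_tail=pd.Series({"m": 0.0}),
        )

    def test_perfect_fit_is_zero(self):
        t = self._table([0.5, 0.3, 0.2], [0.5, 0.3, 0.2])
        assert gof_rmse_mape(t, "m") == (0.0, 0.0)

    def test_constant_deviation(self):
        t = self._table([0.5, 0.3, 0.2], [0.48, 0.28, 0.18])
        rmse, mape = gof_rmse_mape(t, "m")
        assert rmse == pytest.approx(2.0)
        assert mape == pytest.approx(2.0)

    def test_three_cell_example(self):
        t = self._table([0.5, 0.3, 0.2], [0.49, 0.32, 0.18])
        rmse, mape = gof_rmse_mape(t, "m")
        assert rmse == pytest.approx(100 * np.sqrt(0.0009 / 3))
        assert mape == pytest.approx(100 * 0.05 / 3)

    def test_per_observation_alternative(self):
        t = self._table([0.5, 0.3, 0.2], [0.45, 0.3, 0.2])
        y = np.array([0, 0, 1])
        ds = CountDataset(y, np.ones((3, 1)), ["const"])
        rmse, mape = gof_rmse_mape(t, "m", per_observation=True, dataset=ds)
        assert mape == pytest.approx(100 * (0.05 + 0.05 + 0.0) / 3)


class TestSelectionReport:
    def test_report_assembles_and_declares_best(self, quick_settings):
        ds = toy_dataset("hurdle_nb2", 700, 13, beta={"const": 1.0, "x1": 0.4},
                         gamma={"const": -1.0, "x1": 0.5}, alpha=1.0)
        fits = {
            m: CountModel(ds, m, settings=quick_settings).fit()
            for m in ("poisson", "nb2", "hurdle_nb2")
        }
        report = selection_report(fits, ds, J=10)
        # AIC/BIC identities re-derived from each row's llf and k
        for m, row in report.table.iterrows():
            assert row["aic"] == pytest.approx(-2 * row["llf"] + 2 * row["k"])
            assert row["bic"] == pytest.approx(-2 * row["llf"] + np.log(ds.n) * row["k"])
        assert report.best == "hurdle_nb2"
        names = [t.name for t in report.lr_tests]
        assert "nb2 vs poisson" in names and "hurdle_nb2 vs nb2" in names
        # LR statistics non-negative on the nested pairs
        assert all(t.statistic >= 0 for t in report.lr_tests)
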