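"""In-sample model selection: RESET, LR, Vuong, AIC/BIC, per-count fit.

The battery mirrors common practice for comparing count-regression models:

* a regression specification error test (RESET) for the Poisson mean,
* likelihood-ratio tests for the nested pairs,
* the Vuong normal statistic for non-nested pairs, computed from each
  model's per-observation predicted log-probability of the observed count,
* AIC = -2 lnL + 2k and BIC = -2 lnL + ln(N) k,
* and per-count goodness of fit: observed proportions vs mean predicted
  probabilities for counts 0..J, summarised by RMSE and MAPE over the
  count cells, expressed in percentage points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ._optimize import FitSettings
from .data import CountDataset
from .families import ZI_FAMILIES
from .model import CountModel, CountResults, _fit_count, _nll_count
from ._optimize import DesignScaler

#: two-sided 5% normal critical value used by the Vuong decision rule
VUONG_CRITICAL = float(norm.ppf(0.975))

#: (full, restricted) nested pairs examined by the LR battery
NESTED_PAIRS = (
    ("hurdle_poisson", "poisson"),
    ("nb1", "poisson"),
    ("nb2", "poisson"),
    ("zip", "poisson"),
    ("hurdle_nb1", "nb1"),
    ("hurdle_nb2", "nb2"),
    ("zinb2", "zip"),
)


def chi2_critical(df: int, level: float = 0.01) -> float:
    """Upper chi-square critical value at significance ``level``."""
    return float(chi2.ppf(1.0 - level, df))


@dataclass
class TestResult:
    """Outcome of a single specification or discrimination test."""

    name: str
    statistic: float
    df: int | None = None
    p_value: float | None = None
    favored: str | None = None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "favored": self.favored,
            "note": self.note,
        }


def information_criteria(fit: CountResults, n: int | None = None) -> tuple[float, float]:
    """AIC and BIC from a fit's log-likelihood and parameter count."""
    n = fit.nobs if n is None else n
    aic = -2.0 * fit.llf + 2.0 * fit.k
    bic = -2.0 * fit.llf + np.log(n) * fit.k
    return float(aic), float(bic)


def lr_test(fit_restricted: CountResults, fit_full: CountResults, df: int | None = None) -> TestResult:
    """Likelihood-ratio test of a restricted model against a nesting one.

    The statistic is ``2 * (lnL_full - lnL_restricted)``; the caller is
    responsible for the models actually being nested.
    """
    stat = 2.0 * (fit_full.llf - fit_restricted.llf)
    if stat < -1e-6:
        raise ValueError(
            "negative LR statistic: the nesting model fits worse than the restricted "
            "one, which indicates a convergence failure"
        )
    stat = max(stat, 0.0)
    if df is None:
        df = fit_full.k - fit_restricted.k
    p = float(chi2.sf(stat, df)) if df > 0 else np.nan
    favored = fit_full.family if df > 0 and stat > chi2_critical(df, 0.05) else fit_restricted.family
    return TestResult(
        name=f"{fit_full.family} vs {fit_restricted.family}",
        statistic=float(stat),
        df=int(df),
        p_value=p,
        favored=favored,
    )


def vuong_test(fit1: CountResults, fit2: CountResults, dataset: CountDataset | None = None) -> TestResult:
    """Vuong statistic for two non-nested models on the same observations.

    ``V = mean(m) * sqrt(N) / sd(m)`` with ``m_i`` the difference of the two
    models' log predicted probabilities of the observed count.  The first
    model is favored if V > 1.96, the second if V < -1.96, otherwise the
    test is inconclusive.  No information-criterion correction is applied.
    """
    l1 = fit1.loglikeobs(dataset)
    l2 = fit2.loglikeobs(dataset)
    if l1.size != l2.size:
        raise ValueError("the two fits must be evaluated on the same rows")
    m = l1 - l2
    s = float(m.std(ddof=0))
    if s < 1e-12:
        raise ValueError("Vuong statistic undefined: identical predictive distributions")
    V = float(m.mean() * np.sqrt(m.size) / s)
    if V > VUONG_CRITICAL:
        favored = fit1.family
    elif V < -VUONG_CRITICAL:
        favored = fit2.family
    else:
        favored = None
    note = ""
    if fit1.family in ZI_FAMILIES or fit2.family in ZI_FAMILIES:
        note = "Vuong comparison involving a zero-inflated model; interpret with caution"
        warnings.warn(note, stacklevel=2)
    return TestResult(
        name=f"{fit1.family} vs {fit2.family}", statistic=V, favored=favored, note=note
    )


def reset_test(
    dataset: CountDataset,
    powers=(2, 3, 4),
    basis: str = "mean",
    settings: FitSettings | None = None,
) -> TestResult:
    """Regression specification error test for the Poisson mean.

    Fits the Poisson model, augments the design with powers of its fitted
    values (or of the linear predictor with ``basis='linpred'``), refits,
    and LR-tests the added coefficients jointly against chi-square with one
    degree of freedom per retained power.  Collinear augmentation columns
    are dropped with a warning.
    """
    powers = tuple(powers)
    if not powers:
        raise ValueError("powers must be a non-empty collection of integers >= 2")
    if basis not in ("mean", "linpred"):
        raise ValueError("basis must be 'mean' or 'linpred'")
    settings = settings or FitSettings()
    y = dataset.y.astype(float)
    Sx = DesignScaler(dataset.X)
    Xs = Sx.transform(dataset.X)
    base = _fit_count("poisson", y, Xs, settings)
    eta = Xs @ base.theta
    t = np.exp(np.clip(eta, -30, 30)) if basis == "mean" else eta

    cols = []
    kept = []
    current = Xs
    for pwr in powers:
        cand = (t**pwr).reshape(-1, 1)
        sd = cand.std()
        if sd < 1e-12:
            warnings.warn(f"power {pwr} of fitted values is constant; dropped", stacklevel=2)
            continue
        cand = (cand - cand.mean()) / sd
        trial = np.column_stack([current, cand])
        if np.linalg.matrix_rank(trial) <= np.linalg.matrix_rank(current):
            warnings.warn(f"power {pwr} of fitted values is collinear; dropped", stacklevel=2)
            continue
        current = trial
        cols.append(cand)
        kept.append(pwr)
    if not kept:
        raise ValueError("all augmentation columns were collinear with the design")
    aug = np.column_stack([Xs] + cols)
    start = np.concatenate([base.theta, np.zeros(len(kept))])
    full = _fit_count("poisson", y, aug, settings, start=start)
    stat = max(2.0 * (base.nll - full.nll), 0.0)
    df = len(kept)
    return TestResult(
        name=f"RESET({','.join(map(str, kept))})",
        statistic=float(stat),
        df=df,
        p_value=float(chi2.sf(stat, df)),
        note="" if len(kept) == len(powers) else "collinear powers dropped",
    )


# ---------------------------------------------------------------------------
# per-count goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class ProbFitTable:
    """Observed proportions vs mean predicted probabilities per count 0..J."""

    counts: np.ndarray
    observed: pd.Series
    predicted: pd.DataFrame  # one column per model
    observed_tail: float
    predicted_tail: pd.Series

    def to_frame(self) -> pd.DataFrame:
        df = self.predicted.copy()
        df.insert(0, "observed", self.observed)
        df.index.name = "count"
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def plot(self, ax=None):
        """Bar chart of observed proportions with predicted overlays."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        ax.bar(self.counts, self.observed, width=0.8, alpha=0.4, label="observed")
        for col in self.predicted.columns:
            ax.plot(self.counts, self.predicted[col], marker="o", ms=3, lw=1, label=col)
        ax.set_xlabel("count")
        ax.set_ylabel("probability")
        ax.legend(fontsize=7)
        return ax


def prob_fit_table(fits, dataset: CountDataset, J: int = 20) -> ProbFitTable:
    """Observed proportion and mean predicted probability for counts 0..J."""
    if isinstance(fits, CountResults):
        fits = {fits.family: fits}
    if not isinstance(fits, dict):
        fits = {f.family: f for f in fits}
    counts = np.arange(J + 1)
    n = dataset.n
    observed = pd.Series(
        [float(np.mean(dataset.y == j)) for j in counts], index=counts, name="observed"
    )
    pred = {}
    for label, fit in fits.items():
        pred[label] = [float(fit.predict_prob(int(j), dataset).mean()) for j in counts]
    predicted = pd.DataFrame(pred, index=counts)
    return ProbFitTable(
        counts=counts,
        observed=observed,
        predicted=predicted,
        observed_tail=float(1.0 - observed.sum()),
        predicted_tail=1.0 - predicted.sum(axis=0),
    )


def gof_rmse_mape(
    table: ProbFitTable,
    model: str,
    per_observation: bool = False,
    dataset: CountDataset | None = None,
) -> tuple[float, float]:
    """RMSE and MAPE between observed proportions and predicted probabilities.

    Default reading: deviations are taken over the J+1 count *cells* and
    expressed in percentage points.  The per-observation alternative
    (``per_observation=True``, requires ``dataset``) averages the same cell
    deviation over individual observations instead of cells.
    """
    if model not in table.predicted.columns:
        raise ValueError(f"model {model!r} not in table")
    if table.predicted.empty or len(table.counts) == 0:
        raise ValueError("empty probability table")
    d = table.observed.to_numpy() - table.predicted[model].to_numpy()
    if per_observation:
        if dataset is None:
            raise ValueError("per-observation reading requires the dataset")
        cell = np.clip(dataset.y, 0, int(table.counts.max()))
        d = d[cell]
    rmse = 100.0 * float(np.sqrt(np.mean(d**2)))
    mape = 100.0 * float(np.mean(np.abs(d)))
    return rmse, mape


# ---------------------------------------------------------------------------
# the assembled report
# ---------------------------------------------------------------------------


@dataclass
class SelectionReport:
    """Per-model fit summary plus the LR/Vuong test batteries."""

    table: pd.DataFrame
    lr_tests: list[TestResult]
    vuong_tests: list[TestResult]
    best: str | None
    prob_table: ProbFitTable | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def tests_frame(self) -> pd.DataFrame:
        rows = [dict(kind="LR", **t.to_dict()) for t in self.lr_tests]
        rows += [dict(kind="Vuong", **t.to_dict()) for t in self.vuong_tests]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "table": self.table.reset_index().to_dict(orient="records"),
            "lr_tests": [t.to_dict() for t in self.lr_tests],
            "vuong_tests": [t.to_dict() for t in self.vuong_tests],
            "best": self.best,
        }


def _nested_closure():
    """Transitive closure of the nested pairs, as a set of frozensets."""
    direct = {(f, r) for f, r in NESTED_PAIRS}
    changed = True
    while changed:
        changed = False
        for a, b in list(direct):
            for c, d in list(direct):
                if b == c and (a, d) not in direct:
                    direct.add((a, d))
                    changed = True
    return {frozenset(p) for p in direct}


_NESTED_SET = _nested_closure()


def selection_report(
    fits: dict[str, CountResults], dataset: CountDataset, J: int = 20
) -> SelectionReport:
    """Assemble the in-sample battery for a set of fitted models.

    The best model is the converged fit with the lowest AIC (ties broken by
    BIC); LR tests run over the recognised nested pairs, the Vuong test
    over every remaining pair (pairs involving a zero-inflated family carry
    a caution note).
    """
    table_rows = []
    ptable = prob_fit_table(fits, dataset, J=J)
    for label, fit in fits.items():
        aic, bic = information_criteria(fit)
        rmse, mape = gof_rmse_mape(ptable, label)
        table_rows.append(
            {
                "model": label,
                "k": fit.k,
                "llf": fit.llf,
                "aic": aic,
                "bic": bic,
                "rmse": rmse,
                "mape": mape,
                "converged": fit.converged,
            }
        )
    table = pd.DataFrame(table_rows).set_index("model")

    lr = []
    for full, restricted in NESTED_PAIRS:
        if full in fits and restricted in fits:
            lr.append(lr_test(fits[restricted], fits[full]))

    vuong = []
    labels = list(fits)
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if frozenset((fits[a].family, fits[b].family)) in _NESTED_SET:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    vuong.append(vuong_test(fits[a], fits[b], dataset))
                except ValueError:
                    continue

    converged = table[table["converged"]]
    best = None
    if len(converged):
        best = converged.sort_values(["aic", "bic"]).index[0]
    return SelectionReport(table=table, lr_tests=lr, vuong_tests=vuong, best=best, prob_table=ptable)
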