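"""Unconditional marginal effects and profile probabilities for hurdle fits.

The quantity of interest is the unconditional expected count of a two-part
model, E[y|x] = (1 - pi(x)) * E[y | y > 0, x], combining the zero part's
fitted probability of zero with the zero-truncated mean of the count part.
Average marginal effects (AMEs) on this quantity are discrete 0->1 changes
for binary covariates and central-difference derivatives for continuous
ones, averaged over the sample.  Uncertainty comes from a nonparametric
pairs bootstrap that refits both parts on each resample, preserving the
dependence between the separately estimated parts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data import CountDataset
from .families import HURDLE_FAMILIES
from .model import CountModel, CountResults


def _require_hurdle(fit: CountResults):
    if fit.family not in HURDLE_FAMILIES:
        raise ValueError(f"expected a hurdle-family fit, got {fit.family!r}")
    if not fit.params:
        raise ValueError("fit carries no parameters")


def hurdle_unconditional_mean(fit: CountResults, dataset: CountDataset | None = None) -> np.ndarray:
    """Per-row unconditional expected count of a hurdle fit.

    Equals ``(1 - pi) * mu / (1 - f2(0))`` with ``pi`` the fitted zero
    probability and ``f2`` the untruncated count density.
    """
    _require_hurdle(fit)
    return fit.predict_mean(dataset)


def _binary_columns(dataset: CountDataset) -> set[str]:
    names = set(dataset.xnames[1:]) | set(dataset.znames[1:])
    out = set()
    for nm in names:
        col = None
        if nm in dataset.xnames:
            col = dataset.X[:, dataset.xnames.index(nm)]
        else:
            col = dataset.Z[:, dataset.znames.index(nm)]
        if np.all(np.isin(col, (0.0, 1.0))):
            out.add(nm)
    return out


def _ame_point(fit: CountResults, dataset: CountDataset, columns=None) -> pd.Series:
    """Point average marginal effects on the unconditional mean."""
    binary = _binary_columns(dataset)
    names = [
        nm
        for nm in dict.fromkeys(dataset.xnames[1:] + dataset.znames[1:])
        if columns is None or nm in columns
    ]
    out = {}
    for nm in names:
        if nm in binary:
            hi = fit.predict_mean(dataset.with_column(nm, 1.0)).mean()
            lo = fit.predict_mean(dataset.with_column(nm, 0.0)).mean()
            out[nm] = hi - lo
        else:
            col = (
                dataset.X[:, dataset.xnames.index(nm)]
                if nm in dataset.xnames
                else dataset.Z[:, dataset.znames.index(nm)]
            )
            scale = max(float(col.std()), 1.0)
            h = 1e-5 * scale
            hi = fit.predict_mean(dataset.with_column(nm, col + h)).mean()
            lo = fit.predict_mean(dataset.with_column(nm, col - h)).mean()
            out[nm] = (hi - lo) / (2.0 * h)
    return pd.Series(out)


@dataclass
class MarginalEffectsTable:
    """AMEs on the unconditional expected count with bootstrap uncertainty."""

    table: pd.DataFrame
    B: int
    n_failed: int = 0

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MarginalEffectsTable(B={self.B}, failed={self.n_failed})\n{self.table}"


def average_marginal_effects(
    fit: CountResults,
    dataset: CountDataset | None = None,
    B: int = 500,
    seed: int = 0,
    columns=None,
    max_failure_rate: float = 0.2,
) -> MarginalEffectsTable:
    """Sample-average marginal effects of a hurdle fit, with pairs bootstrap.

    Binary covariates get the average discrete 0->1 change of the
    unconditional mean; continuous covariates the average central-difference
    derivative.  ``B`` bootstrap resamples refit both parts and rebuild the
    AME; standard errors are bootstrap standard deviations and p-values are
    normal-approximation two-sided.  ``B=0`` returns point estimates with
    the uncertainty columns flagged unavailable (NaN).
    """
    _require_hurdle(fit)
    dataset = dataset or fit.model.dataset
    binary = _binary_columns(dataset)
    point = _ame_point(fit, dataset, columns)
    kinds = ["discrete change" if nm in binary else "derivative" for nm in point.index]

    if B == 0:
        table = pd.DataFrame(
            {"effect": point, "se": np.nan, "p_value": np.nan, "kind": kinds}
        )
        table.index.name = "covariate"
        return MarginalEffectsTable(table=table, B=0)

    rng = np.random.default_rng(seed)
    draws = []
    failed = 0
    for _ in range(B):
        idx = rng.integers(0, dataset.n, size=dataset.n)
        sub = dataset.subset(idx)
        try:
            refit = CountModel(sub, fit.family, settings=fit.model.settings).fit()
            if not refit.converged:
                failed += 1
                continue
            draws.append(_ame_point(refit, sub, columns))
        except Exception:  # noqa: BLE001 - count and move on
            failed += 1
    if failed > max_failure_rate * B:
        raise RuntimeError(
            f"bootstrap failure rate {failed}/{B} exceeds {max_failure_rate:.0%}; "
            "the model is too fragile on resamples of this dataset"
        )
    boot = pd.DataFrame(draws)
    se = boot.std(ddof=1)
    z = point / se
    table = pd.DataFrame(
        {
            "effect": point,
            "se": se,
            "p_value": 2.0 * norm.sf(np.abs(z)),
            "kind": kinds,
        }
    )
    table.index.name = "covariate"
    return MarginalEffectsTable(table=table, B=B, n_failed=failed)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def standard_profiles(dataset: CountDataset, age_bands=((60, 69), (70, 79), (80, 100))) -> pd.DataFrame:
    """Six age-sex profiles crossed with insurance status.

    Continuous covariates are fixed at sample means, binary and indicator
    covariates at their sample mode; age is set to each band midpoint (with
    ``age_sq`` kept consistent) and ``female``/``insurance`` are varied.
    Requires the corresponding columns in the count-part design.
    """
    names = dataset.xnames[1:]
    for required in ("age", "female", "insurance"):
        if required not in names:
            raise ValueError(f"profiles need an {required!r} covariate")
    binary = _binary_columns(dataset)
    base = {}
    for nm in names:
        col = dataset.X[:, dataset.xnames.index(nm)]
        base[nm] = float(np.round(col.mean())) if nm in binary else float(col.mean())
    rows = []
    labels = []
    for shi in (0.0, 1.0):
        for sex, sexlab in ((1.0, "F"), (0.0, "M")):
            for lo, hi in age_bands:
                mid = (lo + hi) / 2.0
                row = dict(base)
                row["age"] = mid
                if "age_sq" in row:
                    row["age_sq"] = mid**2
                row["female"] = sex
                row["insurance"] = shi
                rows.append(row)
                labels.append(f"{sexlab}{lo}-{hi}, {'with' if shi else 'without'} SHI")
    return pd.DataFrame(rows, index=labels)


def profile_probabilities(
    fit: CountResults, profiles: pd.DataFrame, max_count: int = 10
) -> pd.DataFrame:
    """Predicted probability of each count 0..max_count per covariate profile.

    Rows are profiles, columns counts; partial sums over the reported
    counts are at most one (the remaining mass sits beyond ``max_count``).
    """
    ds = fit.model.dataset
    missing = [c for c in ds.xnames[1:] if c not in profiles.columns]
    if missing:
        raise ValueError(f"profiles lack covariates {missing}")
    X = np.column_stack(
        [np.ones(len(profiles))] + [profiles[c].to_numpy(dtype=float) for c in ds.xnames[1:]]
    )
    zmissing = [c for c in ds.znames[1:] if c not in profiles.columns]
    if zmissing:
        raise ValueError(f"profiles lack zero-part covariates {zmissing}")
    Z = np.column_stack(
        [np.ones(len(profiles))] + [profiles[c].to_numpy(dtype=float) for c in ds.znames[1:]]
    )
    pseudo = CountDataset(np.zeros(len(profiles), dtype=int), X, ds.xnames, Z, ds.znames)
    out = pd.DataFrame(
        {j: fit.predict_prob(j, pseudo) for j in range(max_count + 1)}, index=profiles.index
    )
    out.columns.name = "count"
    return out
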