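"""K-fold cross-validation by held-out log-likelihood.

Rows are partitioned once into K folds of near-equal size; every model is
trained on the same K-1 folds and scored by the log-likelihood its trained
parameters assign to the held-out fold.  Models are compared through the
per-fold difference to a baseline (NB2 by convention), so a positive
difference means the model explains the validation fold better than the
baseline does.  Held-out log-likelihoods are reported as per-fold sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CountDataset
from .model import CountModel, ModelSpec


@dataclass
class FoldAssignment:
    """An immutable random partition of n rows into K folds (labels 1..K)."""

    K: int
    fold: np.ndarray
    seed: int

    @property
    def n(self) -> int:
        return int(self.fold.size)

    def indices(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(train, validation) row indices for fold k in 1..K."""
        mask = self.fold == k
        return np.flatnonzero(~mask), np.flatnonzero(mask)


def kfold_split(n: int, K: int = 10, seed: int = 0) -> FoldAssignment:
    """Uniform random partition of ``n`` rows into ``K`` folds.

    Fold sizes differ by at most one; the assignment is reproducible under
    the seed and is meant to be shared by every model in a comparison.
    """
    if not (2 <= K <= n):
        raise ValueError(f"need 2 <= K <= n, got K={K}, n={n}")
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=np.int64)
    fold[rng.permutation(n)] = np.arange(n) % K + 1
    return FoldAssignment(K=K, fold=fold, seed=seed)


def _as_spec(spec) -> ModelSpec:
    return spec if isinstance(spec, ModelSpec) else ModelSpec(str(spec))


def cv_heldout_loglik(spec, dataset: CountDataset, folds: FoldAssignment) -> pd.DataFrame:
    """Held-out log-likelihood rows (one per fold) for a single model.

    Per fold: fit on the other K-1 folds, then evaluate the fitted
    parameters' log-likelihood on the validation fold.  A fold whose
    training fit fails to converge (or errors) yields a missing value with
    a warning rather than aborting.
    """
    spec = _as_spec(spec)
    if folds.n != dataset.n:
        raise ValueError("fold assignment does not match the dataset")
    rows = []
    for k in range(1, folds.K + 1):
        train, valid = folds.indices(k)
        heldout = np.nan
        converged = False
        try:
            fit = CountModel.from_spec(spec, dataset.subset(train)).fit()
            converged = fit.converged
            if converged:
                heldout = fit.loglike(dataset.subset(valid))
            else:
                warnings.warn(
                    f"{spec.family}: training fit did not converge on fold {k}; "
                    "recorded as missing",
                    stacklevel=2,
                )
        except Exception as exc:  # noqa: BLE001 - contract: record, do not abort
            warnings.warn(f"{spec.family}: fold {k} failed ({exc}); recorded as missing",
                          stacklevel=2)
        rows.append(
            {"fold": k, "model": spec.family, "n_valid": valid.size,
             "heldout_llf": heldout, "converged": converged}
        )
    return pd.DataFrame(rows)


@dataclass
class CVResult:
    """Tidy per-fold held-out log-likelihoods and differences vs baseline."""

    table: pd.DataFrame
    baseline: str
    K: int

    def wins(self) -> pd.Series:
        """Number of folds each model attains the highest held-out lnL."""
        wide = self.table.pivot(index="fold", columns="model", values="heldout_llf")
        winners = wide.idxmax(axis=1, skipna=True)
        return winners.value_counts().reindex(wide.columns, fill_value=0)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def plot(self, ax=None):
        """Grouped bars of per-fold log-likelihood differences vs baseline."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        sub = self.table[self.table["model"] != self.baseline]
        models = sub["model"].unique()
        width = 0.8 / max(len(models), 1)
        for i, m in enumerate(models):
            rows = sub[sub["model"] == m]
            ax.bar(rows["fold"] + (i - len(models) / 2) * width, rows["diff_vs_baseline"],
                   width=width, label=m)
        ax.axhline(0, color="k", lw=0.8)
        ax.set_xlabel("fold")
        ax.set_ylabel(f"held-out lnL difference vs {self.baseline}")
        ax.legend(fontsize=8)
        return ax


def cv_compare(specs, dataset: CountDataset, folds: FoldAssignment, baseline: str = "nb2") -> CVResult:
    """Cross-validate several models on one shared fold assignment.

    Differences are taken fold-by-fold against the baseline model, which
    must be among the compared specs; folds where either side is missing
    are excluded pairwise with a warning.
    """
    specs = [_as_spec(s) for s in specs]
    families = [s.family for s in specs]
    if baseline not in families:
        raise ValueError(f"baseline {baseline!r} is not among the compared models")
    tables = [cv_heldout_loglik(s, dataset, folds) for s in specs]
    table = pd.concat(tables, ignore_index=True)
    base = table[table["model"] == baseline].set_index("fold")["heldout_llf"]
    diffs = []
    for _, row in table.iterrows():
        b = base.get(row["fold"], np.nan)
        d = row["heldout_llf"] - b
        diffs.append(d)
    table["diff_vs_baseline"] = diffs
    missing = table["heldout_llf"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} fold evaluations missing; differences excluded pairwise",
            stacklevel=2,
        )
    return CVResult(table=table, baseline=baseline, K=folds.K)
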