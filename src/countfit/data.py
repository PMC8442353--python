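"""The person-level count dataset container and its CSV plumbing.

A :class:`CountDataset` bundles the non-negative integer outcome ``y`` with
the count-part design matrix ``X`` (intercept first) and an optional
zero-part design ``Z`` (defaults to ``X``), plus column names.  Everything
downstream (fitting, selection, cross-validation, effects) works on this
container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

INTERCEPT = "const"


class ValidationError(ValueError):
    """Raised when inputs violate the dataset contract."""


def _check_counts(y) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValidationError("outcome must be one-dimensional")
    yf = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(yf)):
        raise ValidationError("outcome contains non-finite values")
    if np.any(yf != np.floor(yf)) or np.any(yf < 0):
        raise ValidationError("outcome must be non-negative integers")
    return yf.astype(np.int64)


@dataclass
class CountDataset:
    """Outcome counts plus count-part (X) and zero-part (Z) design matrices."""

    y: np.ndarray
    X: np.ndarray
    xnames: list[str]
    Z: np.ndarray | None = None
    znames: list[str] | None = None

    def __post_init__(self):
        self.y = _check_counts(self.y)
        self.X = np.asarray(self.X, dtype=float)
        self.xnames = list(self.xnames)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValidationError("X must be 2-D with one row per outcome")
        if self.X.shape[1] != len(self.xnames):
            raise ValidationError("xnames must match the columns of X")
        if self.Z is None:
            self.Z = self.X
            self.znames = list(self.xnames)
        else:
            self.Z = np.asarray(self.Z, dtype=float)
            self.znames = list(self.znames if self.znames is not None else self.xnames)
            if self.Z.ndim != 2 or self.Z.shape[0] != self.y.size:
                raise ValidationError("Z must be 2-D with one row per outcome")
            if self.Z.shape[1] != len(self.znames):
                raise ValidationError("znames must match the columns of Z")
        for M, names, label in ((self.X, self.xnames, "X"), (self.Z, self.znames, "Z")):
            if not np.allclose(M[:, 0], 1.0):
                raise ValidationError(f"{label} must carry an intercept in its first column")

    @property
    def n(self) -> int:
        return int(self.y.size)

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        covariates: list[str] | None = None,
        zero_covariates: list[str] | None = None,
    ) -> "CountDataset":
        """Build a dataset from a tidy table, adding the intercept column.

        ``zero_covariates`` defaults to the count-part covariates, i.e. the
        same regressors enter both parts of two-part families.
        """
        if outcome not in data.columns:
            raise ValidationError(f"outcome column {outcome!r} not in table")
        if covariates is None:
            covariates = [c for c in data.columns if c != outcome]
        missing = [c for c in covariates if c not in data.columns]
        if missing:
            raise ValidationError(f"covariate columns missing from table: {missing}")
        y = data[outcome].to_numpy()
        X = np.column_stack([np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in covariates])
        xnames = [INTERCEPT] + list(covariates)
        if zero_covariates is None:
            return cls(y, X, xnames)
        missing = [c for c in zero_covariates if c not in data.columns]
        if missing:
            raise ValidationError(f"zero-part columns missing from table: {missing}")
        Z = np.column_stack(
            [np.ones(len(data))] + [data[c].to_numpy(dtype=float) for c in zero_covariates]
        )
        znames = [INTERCEPT] + list(zero_covariates)
        return cls(y, X, xnames, Z, znames)

    def subset(self, idx) -> "CountDataset":
        idx = np.asarray(idx)
        return CountDataset(self.y[idx], self.X[idx], self.xnames, self.Z[idx], self.znames)

    def with_column(self, name: str, values) -> "CountDataset":
        """Return a copy with covariate ``name`` replaced in X and/or Z."""
        values = np.broadcast_to(np.asarray(values, dtype=float), (self.n,)).copy()
        X, Z = self.X, self.Z
        found = False
        if name in self.xnames:
            X = X.copy()
            X[:, self.xnames.index(name)] = values
            found = True
        if name in self.znames:
            Z = Z.copy()
            Z[:, self.znames.index(name)] = values
            found = True
        if not found:
            raise ValidationError(f"column {name!r} not present in either design")
        return CountDataset(self.y, X, self.xnames, Z, self.znames)

    def to_frame(self, outcome: str = "visits") -> pd.DataFrame:
        df = pd.DataFrame(self.X[:, 1:], columns=self.xnames[1:])
        df.insert(0, outcome, self.y)
        return df

    def to_csv(self, path, outcome: str = "visits") -> None:
        self.to_frame(outcome).to_csv(path, index=False)


def make_dataset(covariates: pd.DataFrame, counts) -> CountDataset:
    """Bundle a covariate table and a count vector into a CountDataset."""
    counts = np.asarray(counts)
    if len(covariates) != counts.size:
        raise ValidationError(
            f"covariates ({len(covariates)} rows) and counts ({counts.size}) differ in length"
        )
    df = covariates.copy()
    df["_y"] = counts
    return CountDataset.from_dataframe(df, outcome="_y", covariates=list(covariates.columns))


def read_dataset(
    path,
    outcome: str,
    covariates: list[str] | None = None,
    categorical: dict[str, object] | None = None,
    zero_covariates: list[str] | None = None,
) -> CountDataset:
    """Read a CSV into a CountDataset.

    ``categorical`` maps column names to their reference level; each such
    column is expanded to indicator columns against that reference.
    """
    df = pd.read_csv(path)
    if categorical:
        covariates = list(covariates) if covariates is not None else [
            c for c in df.columns if c != outcome
        ]
        for col, ref in categorical.items():
            if col not in df.columns:
                raise ValidationError(f"categorical column {col!r} not in table")
            levels = [lv for lv in pd.unique(df[col]) if lv != ref]
            if ref not in set(pd.unique(df[col])):
                raise ValidationError(f"reference level {ref!r} absent from column {col!r}")
            newcols = []
            for lv in levels:
                name = f"{col}_{lv}"
                df[name] = (df[col] == lv).astype(float)
                newcols.append(name)
            covariates = [c for c in covariates if c != col] + newcols
    return CountDataset.from_dataframe(df, outcome, covariates, zero_covariates)
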