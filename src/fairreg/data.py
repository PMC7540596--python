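"""Person-level risk-adjustment data: outcome, design matrix, protected group.

The central container is :class:`RiskAdjustmentDataset`, the (Y, X, A) triple
used throughout the package: an annual spending outcome per person, a design
matrix of demographics and binary condition indicators, and a 0/1 indicator of
membership in the protected (potentially undercompensated) group g.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RiskAdjustmentDataset", "load_dataset"]


def _as_1d_float(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite or missing values")
    return arr


def validate_group_indicator(a, n: int | None = None) -> np.ndarray:
    """Validate a protected-group indicator: 0/1 values, both groups non-empty."""
    arr = np.asarray(a)
    if arr.ndim != 1:
        raise ValueError(f"group indicator must be one-dimensional, got shape {arr.shape}")
    if n is not None and arr.shape[0] != n:
        raise ValueError(f"group indicator has length {arr.shape[0]}, expected {n}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError("group indicator must contain only 0/1 values")
    out = arr.astype(int)
    if out.sum() == 0:
        raise ValueError("protected group g is empty")
    if out.sum() == out.shape[0]:
        raise ValueError("complement group gc is empty")
    return out


@dataclass
class RiskAdjustmentDataset:
    """The (Y, X, A) triple of a risk-adjustment problem.

    Parameters
    ----------
    y : array of shape (n,)
        Continuous outcome per person (annual spending, currency units).
    X : array of shape (n, p) or DataFrame
        Design matrix (demographics + binary condition indicators). An
        intercept column is *not* expected here; estimators add one by
        default.
    a : array of shape (n,)
        Binary indicator of membership in the protected group g.
    columns : list of str, optional
        Design-column names; taken from ``X`` when it is a DataFrame.
    """

    y: np.ndarray
    X: np.ndarray
    a: np.ndarray
    columns: list[str] = field(default=None)

    def __post_init__(self):
        if isinstance(self.X, pd.DataFrame):
            if self.columns is None:
                self.columns = [str(c) for c in self.X.columns]
            self.X = self.X.to_numpy(dtype=float)
        else:
            self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be two-dimensional, got shape {self.X.shape}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite or missing values")
        self.y = _as_1d_float(self.y, "y")
        n = self.y.shape[0]
        if self.X.shape[0] != n:
            raise ValueError(
                f"row mismatch: y has {n} rows, X has {self.X.shape[0]}"
            )
        self.a = validate_group_indicator(self.a, n)
        if self.columns is None:
            self.columns = [f"x{j}" for j in range(self.X.shape[1])]
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("columns length does not match X width")

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def n_g(self) -> int:
        return int(self.a.sum())

    @property
    def n_gc(self) -> int:
        return self.n - self.n_g

    @property
    def p_group(self) -> float:
        """Empirical P(A=1), always the in-sample group proportion."""
        return self.n_g / self.n

    def subset(self, idx) -> "RiskAdjustmentDataset":
        idx = np.asarray(idx)
        return RiskAdjustmentDataset(
            y=self.y[idx], X=self.X[idx], a=self.a[idx], columns=list(self.columns)
        )

    def to_frame(
        self, outcome: str = "y", group: str = "group"
    ) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.columns)
        df[group] = self.a
        df[outcome] = self.y
        return df

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        outcome: str = "y",
        group: str = "group",
        features: list[str] | None = None,
    ) -> "RiskAdjustmentDataset":
        for col in (outcome, group):
            if col not in df.columns:
                raise KeyError(f"column {col!r} not found in data")
        if features is None:
            features = [c for c in df.columns if c not in (outcome, group)]
        missing = [c for c in features if c not in df.columns]
        if missing:
            raise KeyError(f"feature columns not found in data: {missing}")
        return cls(
            y=df[outcome].to_numpy(dtype=float),
            X=df[features].to_numpy(dtype=float),
            a=df[group].to_numpy(),
            columns=list(features),
        )


def load_dataset(
    path,
    outcome: str = "y",
    group: str = "group",
    features: list[str] | None = None,
    sep: str = ",",
) -> RiskAdjustmentDataset:
    """Read a delimited text file with a header into a RiskAdjustmentDataset."""
    df = pd.read_csv(path, sep=sep)
    return RiskAdjustmentDataset.from_frame(
        df, outcome=outcome, group=group, features=features
    )
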