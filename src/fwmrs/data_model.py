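"""Tabular data containers, schema validation, encoding and standardization.

Debiasing always involves (at least) two tables drawn from the same
population that must live in one shared numeric feature space: the
non-representative sample ``N`` (carrying the downstream outcome), the
representative reference ``R`` (no outcome), and optionally an untouched
test split ``T``.  :class:`Dataset` validates a single table;
:class:`TableEncoder` fits a shared one-hot + z-score encoding on the pooled
rows of several datasets so that kernel and linear methods see commensurate
features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

ROLES = ("nonrepresentative", "representative", "test")

__all__ = [
    "Dataset",
    "SampleWeights",
    "FeatureWeights",
    "TableEncoder",
    "load_dataset",
    "fit_encoding",
    "apply_encoding",
]


class SchemaError(ValueError):
    """A table violates the structural contract (missing values, bad outcome...)."""


@dataclass
class Dataset:
    """A validated feature table with an optional binary outcome and a role.

    Parameters
    ----------
    table : pandas.DataFrame
        Feature columns only (the outcome is held separately).  Categorical
        columns are any column with non-numeric dtype.
    outcome : ndarray of {0, 1}, optional
        Downstream binary label, one entry per row.  Only the
        non-representative sample carries it; the representative reference
        structurally withholds it.
    role : {"nonrepresentative", "representative", "test"}
    """

    table: pd.DataFrame
    outcome: np.ndarray | None = None
    role: str = "nonrepresentative"

    def __post_init__(self) -> None:
        if not isinstance(self.table, pd.DataFrame):
            self.table = pd.DataFrame(self.table)
        if self.role not in ROLES:
            raise SchemaError(f"role must be one of {ROLES}, got {self.role!r}")
        if self.table.shape[0] == 0 or self.table.shape[1] == 0:
            raise SchemaError("empty table")
        cols = list(self.table.columns)
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate column names")
        isna = self.table.isna()
        if isna.to_numpy().any():
            row = int(np.argmax(isna.any(axis=1).to_numpy()))
            col = isna.columns[isna.iloc[row].to_numpy().argmax()]
            raise SchemaError(f"missing value at row {row}, column {col!r}")
        if self.outcome is not None:
            y = np.asarray(self.outcome)
            if y.shape != (len(self.table),):
                raise SchemaError(
                    f"outcome length {y.shape} does not match row count {len(self.table)}"
                )
            vals = np.unique(y)
            if not np.isin(vals, [0, 1]).all():
                raise SchemaError(f"outcome must be binary 0/1, found values {vals}")
            self.outcome = y.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.table)

    @property
    def column_names(self) -> list[str]:
        return [str(c) for c in self.table.columns]

    @property
    def categorical_columns(self) -> list[str]:
        return [
            str(c)
            for c in self.table.columns
            if not pd.api.types.is_numeric_dtype(self.table[c])
        ]

    @property
    def values(self) -> np.ndarray:
        """Numeric matrix; raises if categorical columns are still unencoded."""
        if self.categorical_columns:
            raise SchemaError(
                f"categorical columns {self.categorical_columns} are not encoded"
            )
        return self.table.to_numpy(dtype=np.float64)

    def with_role(self, role: str) -> "Dataset":
        return Dataset(self.table, self.outcome, role)

    def subset(self, idx: np.ndarray) -> "Dataset":
        out = None if self.outcome is None else self.outcome[np.asarray(idx)]
        return Dataset(self.table.iloc[np.asarray(idx)].reset_index(drop=True), out, self.role)


@dataclass
class SampleWeights:
    """Nonnegative per-row weights; a dropped row carries exactly zero."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1:
            raise ValueError("sample weights must be a vector")
        if not np.isfinite(w).all() or (w < 0).any():
            raise ValueError("sample weights must be finite and nonnegative")
        self.weights = w

    def __array__(self, dtype=None, copy=None):
        return self.weights.astype(dtype) if dtype is not None else self.weights

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def active(self) -> np.ndarray:
        return self.weights > 0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.weights))


@dataclass
class FeatureWeights:
    """A simplex vector over encoded feature columns, as produced by softmin.

    ``temperature`` records the softmin temperature that produced the vector
    (``inf`` for the exact uniform vector used by plain subsampling).
    """

    weights: np.ndarray
    temperature: float = float("inf")

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 1 or len(w) == 0:
            raise ValueError("feature weights must be a non-empty vector")
        if (w <= 0).any() or (w > 1).any():
            raise ValueError("feature weights must lie in (0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"feature weights must sum to 1, got {w.sum()!r}")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive")
        self.weights = w

    def __array__(self, dtype=None, copy=None):
        return self.weights.astype(dtype) if dtype is not None else self.weights

    def __len__(self) -> int:
        return len(self.weights)

    @classmethod
    def uniform(cls, p: int) -> "FeatureWeights":
        return cls(np.full(p, 1.0 / p), temperature=float("inf"))


def load_dataset(
    path, role: str = "nonrepresentative", outcome_column: str | None = None
) -> Dataset:
    """Read a delimited text table (one header row) into a validated Dataset.

    ``outcome_column``, when given, is split off as the binary outcome and
    removed from the feature table.
    """
    df = pd.read_csv(path)
    if df.shape[0] == 0:
        raise SchemaError(f"empty table: {path}")
    outcome = None
    if outcome_column is not None:
        if outcome_column not in df.columns:
            raise SchemaError(f"outcome column {outcome_column!r} not in {list(df.columns)}")
        outcome = df[outcome_column].to_numpy()
        df = df.drop(columns=[outcome_column])
    return Dataset(df, outcome, role)


class TableEncoder(TransformerMixin, BaseEstimator):
    """Shared one-hot + pooled z-score encoding for a family of datasets.

    Categorical columns are expanded into one indicator column per level,
    using the union of levels across all datasets seen at fit time (levels
    sorted lexicographically; original column order preserved).
    Standardization parameters (mean, sd) are computed on the pooled rows of
    all fit datasets so every dataset is mapped into the same space — there
    is deliberately no per-dataset centering, since the whole point is to
    compare the datasets' distributions.

    Parameters
    ----------
    standardize : bool, default True
        Whether :meth:`transform` z-scores the encoded columns.  Kernel and
        linear methods need it; trees are scale-invariant and receive raw
        encodings.
    """

    def __init__(self, standardize: bool = True):
        self.standardize = standardize

    def fit(self, datasets: Sequence[Dataset] | Dataset, y=None):
        if isinstance(datasets, Dataset):
            datasets = [datasets]
        datasets = list(datasets)
        if not datasets:
            raise ValueError("need at least one dataset")
        cols = datasets[0].column_names
        for d in datasets[1:]:
            if d.column_names != cols:
                raise SchemaError(
                    f"schema mismatch: {cols} vs {d.column_names}"
                )
        cat_cols = set()
        for d in datasets:
            cat_cols.update(d.categorical_columns)
        self.input_columns_ = cols
        self.categorical_levels_: dict[str, list[str]] = {}
        for c in cols:
            if c in cat_cols:
                levels: set[str] = set()
                for d in datasets:
                    levels.update(str(v) for v in d.table[c].unique())
                self.categorical_levels_[c] = sorted(levels)
        encoded_cols: list[str] = []
        self.encoding_map_: dict[str, list[int]] = {}
        for c in cols:
            if c in self.categorical_levels_:
                idx = []
                for lv in self.categorical_levels_[c]:
                    idx.append(len(encoded_cols))
                    encoded_cols.append(f"{c}={lv}")
                self.encoding_map_[c] = idx
            else:
                self.encoding_map_[c] = [len(encoded_cols)]
                encoded_cols.append(c)
        self.columns_ = encoded_cols
        pooled = np.vstack([self._encode_raw(d) for d in datasets])
        self.center_ = pooled.mean(axis=0)
        sd = pooled.std(axis=0, ddof=0)
        # constant columns keep scale 1 so they map to exactly 0
        self.scale_ = np.where(sd > 0, sd, 1.0)
        return self

    def _encode_raw(self, dataset: Dataset) -> np.ndarray:
        if dataset.column_names != self.input_columns_:
            raise SchemaError(
                f"schema mismatch: expected {self.input_columns_}, got {dataset.column_names}"
            )
        out = np.empty((dataset.n_samples, len(self.columns_)), dtype=np.float64)
        for c in self.input_columns_:
            idx = self.encoding_map_[c]
            if c in self.categorical_levels_:
                col = dataset.table[c].astype(str).to_numpy()
                levels = self.categorical_levels_[c]
                unseen = set(col) - set(levels)
                if unseen:
                    raise SchemaError(
                        f"unseen level(s) {sorted(unseen)} in column {c!r}"
                    )
                for j, lv in zip(idx, levels):
                    out[:, j] = col == lv
            else:
                out[:, idx[0]] = dataset.table[c].to_numpy(dtype=np.float64)
        return out

    def transform(self, dataset: Dataset, standardize: bool | None = None) -> Dataset:
        if not hasattr(self, "columns_"):
            raise RuntimeError("TableEncoder is not fitted")
        X = self._encode_raw(dataset)
        do_std = self.standardize if standardize is None else standardize
        if do_std:
            X = (X - self.center_) / self.scale_
        return Dataset(
            pd.DataFrame(X, columns=self.columns_), dataset.outcome, dataset.role
        )


def fit_encoding(datasets: Sequence[Dataset], standardize: bool = True) -> TableEncoder:
    """Fit a shared encoding on the pooled rows of ``datasets``."""
    return TableEncoder(standardize=standardize).fit(datasets)


def apply_encoding(dataset: Dataset, encoder: TableEncoder, standardize: bool | None = None) -> Dataset:
    """Map ``dataset`` into the encoder's shared numeric space."""
    return encoder.transform(dataset, standardize=standardize)
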