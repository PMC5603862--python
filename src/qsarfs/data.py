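"""Descriptor-table I/O, validation, preprocessing, splitting and the feature budget.

A descriptor table is a compounds x descriptors matrix of real-valued
molecular descriptors plus one activity vector (e.g. pIC50).  Preprocessing
drops constant columns, then thins inter-correlated descriptor pairs; the
activity-ranked systematic split yields training and test partitions whose
activity ranges overlap.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError

__all__ = [
    "DescriptorTable",
    "SplitDataset",
    "PreprocessLog",
    "read_descriptor_table",
    "write_descriptor_table",
    "remove_constant_descriptors",
    "correlation_filter",
    "preprocess",
    "y_rank_split",
    "feature_budget",
]


@dataclass
class DescriptorTable:
    """Validated compounds x descriptors matrix with an activity vector.

    Attributes
    ----------
    compound_ids : list of str
        Unique row identifiers.
    descriptor_names : list of str
        Unique column identifiers, aligned with the columns of ``X``.
    X : ndarray of shape (n_compounds, n_descriptors)
        Descriptor values; must be finite.
    y : ndarray of shape (n_compounds,)
        Activity values (e.g. pIC50); must be finite.
    """

    compound_ids: list[str]
    descriptor_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.descriptor_names = [str(d) for d in self.descriptor_names]
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        n, p = self.X.shape
        if len(self.compound_ids) != n:
            raise DataError(
                f"{len(self.compound_ids)} compound ids for {n} matrix rows"
            )
        if len(self.y) != n:
            raise DataError(f"activity vector length {len(self.y)} != {n} rows")
        if len(self.descriptor_names) != p:
            raise DataError(
                f"{len(self.descriptor_names)} descriptor names for {p} columns"
            )
        if len(set(self.compound_ids)) != n:
            raise DataError("compound ids are not unique")
        if len(set(self.descriptor_names)) != p:
            raise DataError("descriptor names are not unique")
        if not np.all(np.isfinite(self.X)):
            raise DataError("descriptor matrix contains missing/non-finite values")
        if not np.all(np.isfinite(self.y)):
            raise DataError("activity vector contains missing/non-finite values")

    @property
    def n_compounds(self) -> int:
        return self.X.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.X.shape[1]

    def select_columns(self, mask: np.ndarray) -> "DescriptorTable":
        """Return a new table keeping only columns where ``mask`` is True."""
        mask = np.asarray(mask, dtype=bool)
        names = [n for n, m in zip(self.descriptor_names, mask) if m]
        return DescriptorTable(self.compound_ids, names, self.X[:, mask], self.y)

    def select_rows(self, idx: np.ndarray) -> "DescriptorTable":
        """Return a new table keeping only the rows in ``idx`` (in order)."""
        idx = np.asarray(idx)
        ids = [self.compound_ids[i] for i in idx]
        return DescriptorTable(ids, list(self.descriptor_names), self.X[idx], self.y[idx])


@dataclass
class SplitDataset:
    """Train/test partition of one descriptor table."""

    train: DescriptorTable
    test: DescriptorTable
    test_fraction: float

    def __post_init__(self) -> None:
        overlap = set(self.train.compound_ids) & set(self.test.compound_ids)
        if overlap:
            raise DataError(f"train/test compound overlap: {sorted(overlap)[:5]}")
        if self.train.descriptor_names != self.test.descriptor_names:
            raise DataError("train and test descriptor names differ")


@dataclass
class PreprocessLog:
    """Record of descriptors dropped during preprocessing."""

    removed_constant: list[str] = field(default_factory=list)
    removed_correlated: list[tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "removed_constant": list(self.removed_constant),
            "removed_correlated": [
                {"kept": k, "dropped": d, "pearson_r": float(r)}
                for k, d, r in self.removed_correlated
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def merge(self, other: "PreprocessLog") -> "PreprocessLog":
        return PreprocessLog(
            self.removed_constant + other.removed_constant,
            self.removed_correlated + other.removed_correlated,
        )


def read_descriptor_table(path, activity_column: str, id_column: str) -> DescriptorTable:
    """Read a CSV descriptor table.

    Expects a header row, one identifier column, one activity column; every
    remaining column is a numeric descriptor.  Column order is preserved as
    descriptor order.

    Raises
    ------
    ConfigurationError
        If the id or activity column is absent.
    DataError
        If any cell is blank or non-numeric (the offending row/column is named).
    """
    df = pd.read_csv(path)
    for col in (id_column, activity_column):
        if col not in df.columns:
            raise ConfigurationError(f"column {col!r} not found in {path}")
    ids = df[id_column].astype(str).tolist()
    numeric_cols = [c for c in df.columns if c != id_column]
    numeric = {}
    for col in numeric_cols:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna()
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            cell = raw.iloc[i]
            kind = "missing value" if pd.isna(cell) else f"non-numeric value {cell!r}"
            raise DataError(
                f"{kind} at row {i} (compound {ids[i]!r}), column {col!r}"
            )
        numeric[col] = coerced.to_numpy(dtype=float)
    y = numeric.pop(activity_column)
    names = [c for c in numeric_cols if c != activity_column]
    X = np.column_stack([numeric[c] for c in names]) if names else np.empty((len(ids), 0))
    return DescriptorTable(ids, names, X, y)


def write_descriptor_table(
    table: DescriptorTable,
    path,
    activity_column: str = "pIC50",
    id_column: str = "compound_id",
) -> None:
    """Write a table in the CSV layout ``read_descriptor_table`` accepts."""
    df = pd.DataFrame(table.X, columns=table.descriptor_names)
    df.insert(0, activity_column, table.y)
    df.insert(0, id_column, table.compound_ids)
    df.to_csv(path, index=False)


def remove_constant_descriptors(
    table: DescriptorTable,
) -> tuple[DescriptorTable, PreprocessLog]:
    """Drop every descriptor whose value is identical for all compounds."""
    constant = np.array([np.ptp(col) == 0.0 for col in table.X.T], dtype=bool)
    if constant.all() and table.n_descriptors > 0:
        raise DataError("all descriptors are constant; nothing left to select")
    log = PreprocessLog(
        removed_constant=[n for n, c in zip(table.descriptor_names, constant) if c]
    )
    if not constant.any():
        return table, log
    return table.select_columns(~constant), log


def correlation_filter(
    table: DescriptorTable, threshold: float = 0.80
) -> tuple[DescriptorTable, PreprocessLog]:
    """Thin inter-correlated descriptor pairs (|Pearson r| > ``threshold``).

    Columns are scanned left to right; a column correlated above the threshold
    with any already-kept column is dropped (keep-first, deterministic).
    """
    if not (0.0 < threshold <= 1.0):
        raise ConfigurationError(f"correlation threshold must be in (0, 1], got {threshold}")
    for name, col in zip(table.descriptor_names, table.X.T):
        if np.ptp(col) == 0.0:
            raise DataError(f"constant descriptor {name!r}: Pearson r undefined")
    p = table.n_descriptors
    if p < 2:
        return table, PreprocessLog()
    corr = np.corrcoef(table.X, rowvar=False)
    keep: list[int] = []
    log = PreprocessLog()
    for j in range(p):
        offender = None
        for i in keep:
            if abs(corr[i, j]) > threshold:
                offender = i
                break
        if offender is None:
            keep.append(j)
        else:
            log.removed_correlated.append(
                (
                    table.descriptor_names[offender],
                    table.descriptor_names[j],
                    float(corr[offender, j]),
                )
            )
    mask = np.zeros(p, dtype=bool)
    mask[keep] = True
    return table.select_columns(mask), log


def preprocess(
    table: DescriptorTable, threshold: float = 0.80
) -> tuple[DescriptorTable, PreprocessLog]:
    """Constant-column removal followed by the correlation filter."""
    table, log1 = remove_constant_descriptors(table)
    table, log2 = correlation_filter(table, threshold)
    return table, log1.merge(log2)


def y_rank_split(table: DescriptorTable, test_fraction: float = 0.2) -> SplitDataset:
    """Partition compounds by systematic sampling over activity rank.

    Compounds are sorted ascending by activity; every m-th compound in rank
    order (m = round(1/test_fraction), starting at rank ceil(m/2)) goes to the
    test set, so both partitions span the activity range.
    """
    if not (0.0 < test_fraction <= 0.5):
        raise ConfigurationError(
            f"test_fraction must be in (0, 0.5], got {test_fraction}"
        )
    n = table.n_compounds
    if n < 5:
        raise DataError(f"need at least 5 compounds to split, got {n}")
    m = int(round(1.0 / test_fraction))
    offset = math.ceil(m / 2)
    order = np.argsort(table.y, kind="stable")
    test_rank = np.zeros(n, dtype=bool)
    test_rank[offset - 1 :: m] = True
    test_idx = order[test_rank]
    train_idx = order[~test_rank]
    return SplitDataset(
        train=table.select_rows(np.sort(train_idx)),
        test=table.select_rows(np.sort(test_idx)),
        test_fraction=test_fraction,
    )


def feature_budget(n_train: int, fraction: float = 0.2) -> int:
    """Number of descriptors a selector searches for: floor(fraction * n_train), min 1."""
    if n_train < 5:
        raise DataError(f"need at least 5 training compounds, got {n_train}")
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError(f"budget fraction must be in (0, 1), got {fraction}")
    return max(1, math.floor(fraction * n_train))
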