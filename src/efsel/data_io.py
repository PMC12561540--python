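"""Tabular dataset handling: CSV IO, stratified splitting, min-max normalization.

The containers here are deliberately small. A :class:`Dataset` is a dense
feature matrix plus integer class labels; the split and fold helpers return
index sets into it, so no data is ever copied until a classifier needs a
column subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "Dataset",
    "DataSplit",
    "NormalizationParams",
    "DatasetFormatError",
    "ValidationError",
    "load_dataset_csv",
    "write_dataset_csv",
    "stratified_split",
    "fit_minmax",
    "apply_minmax",
    "stratified_kfold",
]


class DatasetFormatError(ValueError):
    """Raised when an input file does not conform to the expected CSV dialect."""


class ValidationError(ValueError):
    """Raised when data violates a contract (class counts, fractions, ...)."""


@dataclass
class Dataset:
    """A classification dataset: instances x features plus integer labels.

    Labels are dense integers ``0..n_classes-1``.  ``n_features`` is the
    denominator of the relative subset-size term in the wrapper fitness.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValidationError("X must be a 2-D matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} labels"
            )
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(self.X.shape[1])]
        if len(self.feature_names) != self.X.shape[1]:
            raise ValidationError("feature_names length does not match X columns")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.y.max()) + 1 if self.y.size else 0

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.y, minlength=self.n_classes)


@dataclass(frozen=True)
class DataSplit:
    """Disjoint train/test index sets covering a dataset exactly once."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


@dataclass(frozen=True)
class NormalizationParams:
    """Per-feature min/max fitted on training rows only (leakage contract)."""

    minimum: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.maximum < self.minimum):
            raise ValidationError("per-feature max must be >= min")


def load_dataset_csv(path: str | Path, label_column: str | int = -1) -> Dataset:
    """Read a comma-separated dataset with a header row.

    Parameters
    ----------
    path:
        CSV file; UTF-8, ``.`` decimal separator, header row required.
    label_column:
        Column name, or integer position into the header (negative allowed).

    Labels are re-encoded to ``0..n_classes-1`` preserving the sorted order of
    the original label values.  A companion ``<stem>.truth.json`` file, if
    present, is ignored here (see :mod:`efsel.synthetic_data`).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=",", encoding="utf-8")
    if isinstance(label_column, int):
        try:
            label_name = df.columns[label_column]
        except IndexError:
            raise DatasetFormatError(
                f"label column index {label_column} out of range for "
                f"{len(df.columns)} columns"
            ) from None
    else:
        if label_column not in df.columns:
            raise DatasetFormatError(f"label column {label_column!r} not found")
        label_name = label_column

    feature_cols = [c for c in df.columns if c != label_name]
    for c in feature_cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        if numeric.isna().any() and not df[c].isna().any():
            raise DatasetFormatError(f"non-numeric value in feature column {c!r}")
        if df[c].isna().any():
            raise DatasetFormatError(f"missing value in feature column {c!r}")
        df[c] = numeric

    raw_labels = df[label_name].to_numpy()
    classes = np.unique(raw_labels)  # sorted original label order
    if classes.size < 2:
        raise ValidationError("dataset must contain at least two classes")
    y = np.searchsorted(classes, raw_labels)
    X = df[feature_cols].to_numpy(dtype=np.float64)
    return Dataset(X=X, y=y, feature_names=list(feature_cols))


def write_dataset_csv(
    ds: Dataset,
    path: str | Path,
    label_column: str = "class",
    truth_mask: np.ndarray | None = None,
) -> None:
    """Write a dataset as CSV; optionally a ``.truth.json`` ground-truth mask."""
    path = Path(path)
    df = pd.DataFrame(ds.X, columns=ds.feature_names)
    df[label_column] = ds.y
    df.to_csv(path, index=False)
    if truth_mask is not None:
        meta = {"informative_or_redundant": [bool(b) for b in truth_mask]}
        path.with_suffix(".truth.json").write_text(json.dumps(meta))


def _largest_remainder_quotas(counts: np.ndarray, fraction: float) -> np.ndarray:
    """Apportion round(fraction * total) slots across classes.

    Largest-remainder rule: floor each class quota, then hand out the
    remaining slots to the classes with the largest fractional parts
    (ties broken by class index for determinism).
    """
    target_total = int(round(fraction * counts.sum()))
    exact = fraction * counts
    base = np.floor(exact).astype(int)
    remainder = exact - base
    missing = target_total - base.sum()
    if missing > 0:
        # stable sort descending by remainder, ascending class index on ties
        order = np.lexsort((np.arange(counts.size), -remainder))
        base[order[:missing]] += 1
    elif missing < 0:
        order = np.lexsort((np.arange(counts.size), remainder))
        base[order[: -missing]] -= 1
    return base


def stratified_split(ds: Dataset, train_fraction: float, seed: int) -> DataSplit:
    """Split instances 'paying attention to the equal division of classes'.

    Per-class train counts follow largest-remainder apportionment of the
    global train quota, so every class train fraction is within one instance
    of ``train_fraction``.  Deterministic given ``seed``.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ValidationError("train_fraction must lie strictly between 0 and 1")
    counts = ds.class_counts()
    for c, cnt in enumerate(counts):
        if cnt < 2:
            raise ValidationError(f"class {c} has {cnt} instance(s); need at least 2")
    quotas = _largest_remainder_quotas(counts, train_fraction)
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for c, q in enumerate(quotas):
        members = np.flatnonzero(ds.y == c)
        members = rng.permutation(members)
        train_parts.append(members[:q])
        test_parts.append(members[q:])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.concatenate(test_parts))
    return DataSplit(train_indices=train, test_indices=test, seed=seed)


def fit_minmax(ds: Dataset, indices: np.ndarray) -> NormalizationParams:
    """Fit per-feature min/max on the given (training) rows only."""
    sub = ds.X[np.asarray(indices)]
    return NormalizationParams(minimum=sub.min(axis=0), maximum=sub.max(axis=0))


def apply_minmax(params: NormalizationParams, ds: Dataset) -> Dataset:
    """Affinely map each feature to [0,1] using fitted train-set ranges.

    Zero-variance features map to 0; values outside the fitted range (test
    rows) are clipped into [0,1] so KNN distances stay bounded.
    """
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    Z = (ds.X - params.minimum) / safe
    Z[:, span == 0] = 0.0
    np.clip(Z, 0.0, 1.0, out=Z)
    return Dataset(X=Z, y=ds.y.copy(), feature_names=list(ds.feature_names))


def stratified_kfold(
    ds: Dataset, indices: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Partition ``indices`` into k stratified (fit, hold) pairs.

    Per-class counts across holds differ by at most one.  Deterministic
    given ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    indices = np.asarray(indices)
    y_sub = ds.y[indices]
    counts = np.bincount(y_sub, minlength=ds.n_classes)
    for c, cnt in enumerate(counts):
        if 0 < cnt < k:
            raise ValidationError(
                f"class {c} has only {cnt} instance(s) in the given indices; "
                f"needs at least k={k} for stratified {k}-fold CV"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fit_loc, hold_loc in skf.split(np.zeros(len(indices)), y_sub):
        folds.append((indices[fit_loc], indices[hold_loc]))
    return folds
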