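"""Labeled high-dimensional matrices: loading, validation, splitting, output.

The central container is :class:`Dataset`, a dense samples x features matrix
with one categorical class label per sample.  Expression matrices are commonly
shipped either samples-as-rows or genes-as-rows; :func:`read_delimited_matrix`
supports both orientations.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Dataset",
    "SplitPair",
    "DataError",
    "read_delimited_matrix",
    "stratified_split",
    "write_selection",
    "read_selection",
]

ORIENT_COLS = "features-as-columns"
ORIENT_ROWS = "features-as-rows"


class DataError(ValueError):
    """Raised on malformed or invalid input data."""


@dataclass
class Dataset:
    """A dense numeric feature matrix with per-sample class labels.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_features)
        Real-valued matrix; missing values are rejected.
    y : array-like of length n_samples
        Class label per sample.  Labels may be strings or integers; class
        order is defined by first appearance in ``y`` and is used everywhere
        a stable class indexing is needed (probability matrices, confusion
        matrices).
    feature_ids, sample_ids : sequences of unique identifiers.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=object)
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.X.ndim != 2:
            raise DataError(f"X must be 2-D, got shape {self.X.shape}")
        n, p = self.X.shape
        if len(self.y) != n:
            raise DataError(f"len(y)={len(self.y)} does not match n_samples={n}")
        if len(self.feature_ids) != p:
            raise DataError(
                f"{len(self.feature_ids)} feature ids for {p} feature columns"
            )
        if len(set(self.feature_ids)) != p:
            raise DataError("feature_ids are not unique")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample_ids are not unique")
        if np.isnan(self.X).any():
            i, j = np.argwhere(np.isnan(self.X))[0]
            raise DataError(
                f"missing value at sample '{self.sample_ids[i]}', "
                f"feature '{self.feature_ids[j]}'"
            )

    # -- basic introspection ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> list:
        """Class labels ordered by first appearance in ``y``."""
        return list(pd.unique(self.y))

    def class_counts(self) -> dict:
        return {c: int(np.sum(self.y == c)) for c in self.classes}

    def require_min_class_size(self, minimum: int = 2) -> None:
        """Fail loudly if any class has fewer than ``minimum`` samples."""
        for c, cnt in self.class_counts().items():
            if cnt < minimum:
                raise DataError(
                    f"class {c!r} has only {cnt} sample(s); need >= {minimum}"
                )

    # -- subsetting ---------------------------------------------------------

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise DataError(f"unknown feature id {feature_id!r}") from None

    def select_features(self, ids: Sequence[str]) -> "Dataset":
        """Restrict to the given features, preserving the order of ``ids``."""
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        try:
            idx = [pos[f] for f in ids]
        except KeyError as e:
            raise DataError(f"unknown feature id {e.args[0]!r}") from None
        return Dataset(self.X[:, idx], self.y, list(ids), self.sample_ids)

    def subset_samples(self, indices: Sequence[int]) -> "Dataset":
        idx = np.asarray(indices, dtype=int)
        return Dataset(
            self.X[idx],
            self.y[idx],
            self.feature_ids,
            [self.sample_ids[i] for i in idx],
        )

    def to_frame(self, label_field: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.X, index=self.sample_ids, columns=self.feature_ids)
        df[label_field] = self.y
        return df


@dataclass
class SplitPair:
    """Disjoint train/test partition of a Dataset sharing the feature axis."""

    train: Dataset
    test: Dataset


def _infer_delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_delimited_matrix(
    path,
    orientation: str = ORIENT_COLS,
    label_field: str = "label",
    delimiter: str | None = None,
) -> Dataset:
    """Read a labeled matrix from delimited text (CSV/TSV).

    The first column (or row, for ``features-as-rows``) holds identifiers.
    ``label_field`` names the column (row) holding the class labels.  Every
    other cell must parse as a number; the first offending cell is reported
    by sample and feature id.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    if orientation not in (ORIENT_COLS, ORIENT_ROWS):
        raise DataError(
            f"orientation must be {ORIENT_COLS!r} or {ORIENT_ROWS!r}, "
            f"got {orientation!r}"
        )
    sep = delimiter if delimiter is not None else _infer_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)

    if orientation == ORIENT_ROWS:
        if label_field not in df.index:
            raise DataError(f"label field {label_field!r} not found")
        df = df.T
    if label_field not in df.columns:
        raise DataError(f"label field {label_field!r} not found")

    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise DataError(f"duplicate identifier {dup!r}")

    y = df[label_field].to_numpy(dtype=object)
    xdf = df.drop(columns=[label_field])
    numeric = xdf.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"non-numeric or missing value {xdf.iat[i, j]!r} at sample "
            f"'{xdf.index[i]}', feature '{xdf.columns[j]}'"
        )

    ds = Dataset(
        numeric.to_numpy(dtype=float),
        y,
        [str(c) for c in xdf.columns],
        [str(s) for s in xdf.index],
    )
    ds.require_min_class_size(2)
    return ds


def stratified_split(ds: Dataset, test_fraction: float = 0.4, seed: int = 0) -> SplitPair:
    """Seeded stratified partition into train and test sets.

    Per-class test counts are ``round(class_count * test_fraction)`` with
    half-up rounding, then repaired so every class keeps at least one sample
    in each partition.  Deterministic for a fixed seed.
    """
    if not 0.0 < test_fraction < 1.0:
        raise DataError(f"test_fraction must lie in (0, 1), got {test_fraction}")
    ds.require_min_class_size(2)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for c in ds.classes:
        idx = np.flatnonzero(ds.y == c)
        n_c = len(idx)
        n_test = int(np.floor(n_c * test_fraction + 0.5))  # round half-up
        n_test = min(max(n_test, 1), n_c - 1)
        perm = rng.permutation(idx)
        test_idx.extend(perm[:n_test].tolist())
    test_idx_sorted = sorted(test_idx)
    train_idx = sorted(set(range(ds.n_samples)) - set(test_idx))
    return SplitPair(ds.subset_samples(train_idx), ds.subset_samples(test_idx_sorted))


_STAGE2_METHODS = ("mi", "relieff", "surf", "surfstar")


def write_selection(result, path) -> None:
    """Write a final feature selection as TSV.

    Columns: feature_id, provenance (``intersection`` or ``gini_added``),
    and the four stage-2 scores of each feature.  The row order is the final
    selection order and round-trips losslessly through :func:`read_selection`.
    """
    final = list(result.final_features)
    if not final:
        raise DataError("selection result is empty")
    inter = set(result.intersection_features)
    rows = []
    for fid in final:
        row = {
            "feature_id": fid,
            "provenance": "intersection" if fid in inter else "gini_added",
        }
        for m in _STAGE2_METHODS:
            scores = (result.stage2_scores or {}).get(m, {})
            row[f"score_{m}"] = scores.get(fid, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_selection(path) -> pd.DataFrame:
    """Read a selection TSV written by :func:`write_selection`."""
    df = pd.read_csv(path, sep="\t")
    expected = ["feature_id", "provenance"] + [f"score_{m}" for m in _STAGE2_METHODS]
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise DataError(f"selection file missing columns: {missing}")
    return df
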