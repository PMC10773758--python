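"""Stage-0 preprocessing: Spearman redundancy removal and standardization.

Highly linearly (monotonically) correlated features carry redundant
information; dropping all but one representative of each correlated group
shrinks the matrix before the expensive filters run.  Redundancy is detected
with Spearman's rank correlation

    r_s = 1 - 6 * sum(d_i^2) / (n * (n^2 - 1))

which, in the presence of ties, generalizes to the Pearson correlation of
average-ranked values — the form implemented here.  Surviving features are
then z-scored, x' = (x - mu) / sigma.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import DataError, Dataset

__all__ = [
    "spearman_rho",
    "spearman_matrix",
    "spearman_redundancy_filter",
    "RedundancyReport",
    "StandardizerParams",
    "fit_standardizer",
    "apply_standardizer",
]


def spearman_rho(x, y) -> float:
    """Spearman rank correlation of two equal-length vectors.

    Ties receive average ranks; the statistic is the Pearson correlation of
    the rank vectors, which reduces to the classical 1 - 6*sum(d^2)/(n(n^2-1))
    form when no ties occur.  If either vector is constant the correlation is
    undefined and 0.0 is returned by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise DataError("need at least 2 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if rx.std() == 0.0 or ry.std() == 0.0:
        return 0.0
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_matrix(X: np.ndarray) -> np.ndarray:
    """Full p x p Spearman correlation matrix of the columns of X.

    Constant columns have correlation 0 against everything (diagonal 1).
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    R = stats.rankdata(X, axis=0)
    sd = R.std(axis=0)
    const = sd == 0.0
    # corrcoef emits NaN for zero-variance columns; patched below.
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(R, rowvar=False)
    C = np.atleast_2d(C)
    C[const, :] = 0.0
    C[:, const] = 0.0
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class RedundancyReport:
    """Outcome of the redundancy filter: surviving ids and drop provenance."""

    kept: list[str]
    dropped: list[tuple[str, str, float]]  # (dropped_id, kept_partner_id, rho)

    @property
    def dropped_ids(self) -> list[str]:
        return [d for d, _, _ in self.dropped]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.dropped, columns=["dropped_id", "kept_partner_id", "rho"]
        )


def spearman_redundancy_filter(
    ds: Dataset, threshold: float = 0.9
) -> tuple[Dataset, RedundancyReport]:
    """Greedily drop features whose |rho| with an earlier kept feature >= threshold.

    Features are scanned in column order; when a pair violates the threshold
    the earlier (already kept) member is retained and the later one dropped,
    recording the earliest kept partner.  Deterministic and order-stable.
    """
    if not 0.0 < threshold <= 1.0:
        raise DataError(f"threshold must lie in (0, 1], got {threshold}")
    rho = spearman_matrix(ds.X)
    kept: list[int] = []
    dropped: list[tuple[str, str, float]] = []
    for j in range(ds.n_features):
        if kept:
            col = np.abs(rho[kept, j])
            hits = np.flatnonzero(col >= threshold)
            if hits.size:
                partner = kept[hits[0]]
                dropped.append(
                    (ds.feature_ids[j], ds.feature_ids[partner], float(rho[partner, j]))
                )
                continue
        kept.append(j)
    kept_ids = [ds.feature_ids[j] for j in kept]
    return ds.select_features(kept_ids), RedundancyReport(kept_ids, dropped)


@dataclass
class StandardizerParams:
    """Per-feature mean and population standard deviation, tied to feature ids."""

    mu: np.ndarray
    sigma: np.ndarray
    feature_ids: list[str]

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.mu) == len(self.sigma) == len(self.feature_ids)):
            raise DataError("standardizer parameter lengths disagree")
        if (self.sigma < 0).any():
            raise DataError("sigma must be non-negative")


def fit_standardizer(train: Dataset) -> StandardizerParams:
    """Fit per-feature mean and population (ddof=0) standard deviation."""
    return StandardizerParams(
        train.X.mean(axis=0), train.X.std(axis=0), list(train.feature_ids)
    )


def apply_standardizer(ds: Dataset, params: StandardizerParams) -> Dataset:
    """z-score each feature; constant features (sigma = 0) map to all zeros."""
    if list(ds.feature_ids) != list(params.feature_ids):
        raise DataError("feature ids do not match the fitted standardizer")
    sigma = np.where(params.sigma == 0.0, 1.0, params.sigma)
    Z = (ds.X - params.mu) / sigma
    Z[:, params.sigma == 0.0] = 0.0
    return Dataset(Z, ds.y, ds.feature_ids, ds.sample_ids)
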