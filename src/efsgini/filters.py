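"""Univariate and instance-based feature scorers.

Stage 1 uses the one-way ANOVA F statistic to cheaply shortlist candidate
features.  Stage 2 runs four filters in parallel on the shortlist:

* mutual information between a discretized feature and the class label
  (plug-in estimator, base-2 logs, so scores are in bits);
* ReliefF — k-nearest-neighbor relief weighting with Kononenko's
  class-prior-weighted misses;
* SURF — relief with a distance threshold T (the mean pairwise distance)
  in place of a fixed neighbor count;
* SURF* — SURF plus a "far" zone (distance > T) scored with inverted sign.

Every scorer returns a :class:`FeatureRanking`: all features of its input,
sorted by non-increasing score, ties broken by ascending column index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .data import DataError, Dataset

__all__ = [
    "FeatureRanking",
    "select_top",
    "f_test_scores",
    "mutual_information_scores",
    "relieff_scores",
    "surf_scores",
    "surfstar_scores",
]


@dataclass
class FeatureRanking:
    """Ordered (feature_id, score) pairs, descending by score."""

    entries: list[tuple[str, float]]
    method: str

    def __post_init__(self):
        scores = [s for _, s in self.entries]
        # non-increasing check; +inf heads compare fine with >=
        for a, b in zip(scores, scores[1:]):
            if not (a >= b or np.isinf(a)):
                raise DataError("ranking scores are not non-increasing")

    @property
    def feature_ids(self) -> list[str]:
        return [f for f, _ in self.entries]

    def scores(self) -> dict[str, float]:
        return dict(self.entries)

    def rank_of(self, feature_id: str) -> int:
        """1-based position of a feature in the ranking."""
        for i, (f, _) in enumerate(self.entries):
            if f == feature_id:
                return i + 1
        raise DataError(f"feature {feature_id!r} not in ranking")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"rank": i + 1, "feature_id": f, "score": s, "method": self.method}
                for i, (f, s) in enumerate(self.entries)
            ]
        )


def _make_ranking(
    feature_ids: list[str],
    scores: np.ndarray,
    method: str,
    inf_secondary: np.ndarray | None = None,
) -> FeatureRanking:
    """Sort descending by score; ties by ascending column index.

    Infinite scores sort first; among themselves they are ordered by the
    descending secondary key (between-group sum of squares for the F-test),
    then column index.
    """
    scores = np.asarray(scores, dtype=float)
    keys = []
    for i, s in enumerate(scores):
        if np.isposinf(s):
            sec = -float(inf_secondary[i]) if inf_secondary is not None else 0.0
            keys.append((-np.inf, sec, i))
        else:
            keys.append((-float(s), 0.0, i))
    order = sorted(range(len(scores)), key=lambda i: keys[i])
    entries = [(feature_ids[i], float(scores[i])) for i in order]
    return FeatureRanking(entries, method)


def select_top(ranking: FeatureRanking, k: int) -> list[str]:
    """First k feature ids of a ranking (stable under the stated tie-break)."""
    if k <= 0:
        raise DataError(f"k must be positive, got {k}")
    if k > len(ranking.entries):
        raise DataError(
            f"k={k} exceeds the {len(ranking.entries)} ranked features"
        )
    return [f for f, _ in ranking.entries[:k]]


# ---------------------------------------------------------------------------
# Stage 1: one-way ANOVA F
# ---------------------------------------------------------------------------

def f_test_scores(ds: Dataset) -> FeatureRanking:
    """Per-feature one-way ANOVA F statistic against the class label.

    F = (SSB / (C-1)) / (SSW / (n-C)).  Features separating the classes
    perfectly (SSW = 0, SSB > 0) score +inf and are ordered first, among
    themselves by descending between-group sum of squares.  Features with
    no between-group variation (including constants) score 0.
    """
    classes = ds.classes
    C = len(classes)
    if C < 2:
        raise DataError("F-test requires at least 2 classes")
    n, p = ds.X.shape
    grand = ds.X.mean(axis=0)
    ssb = np.zeros(p)
    ssw = np.zeros(p)
    for c in classes:
        mask = ds.y == c
        Xc = ds.X[mask]
        mc = Xc.mean(axis=0)
        ssb += mask.sum() * (mc - grand) ** 2
        ssw += ((Xc - mc) ** 2).sum(axis=0)
    sst = ssb + ssw
    # exact-arithmetic zeros can surface as ~1e-30 after the mean subtraction
    tol = 1e-12 * np.maximum(sst, 1e-300)
    zero_b = ssb <= tol
    zero_w = ssw <= tol
    dfb = C - 1
    dfw = n - C
    F = np.zeros(p)
    finite = ~zero_b & ~zero_w
    if dfw > 0:
        F[finite] = (ssb[finite] / dfb) / (ssw[finite] / dfw)
    else:
        F[finite] = np.inf
    F[~zero_b & zero_w] = np.inf
    F[zero_b] = 0.0
    return _make_ranking(ds.feature_ids, F, "f_test", inf_secondary=ssb)


# ---------------------------------------------------------------------------
# Mutual information
# ---------------------------------------------------------------------------

def _equal_frequency_codes(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Discretize into <= n_bins equal-frequency bins (ties may merge bins)."""
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    edges = np.unique(qs)
    return np.searchsorted(edges, x, side="left")


def _plugin_mi_bits(cx: np.ndarray, cy: np.ndarray) -> float:
    """Plug-in mutual information of two code vectors, in bits."""
    n = len(cx)
    kx = cx.max() + 1
    ky = cy.max() + 1
    joint = np.zeros((kx, ky))
    np.add.at(joint, (cx, cy), 1.0)
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def mutual_information_scores(ds: Dataset, n_bins: int = 8) -> FeatureRanking:
    """Mutual information (bits) between each binned feature and the label.

    Continuous features are discretized by equal-frequency binning into at
    most ``n_bins`` bins; the plug-in estimate with base-2 logarithms is then
    computed against the class label.  Constant features score 0.
    """
    if n_bins < 2:
        raise DataError(f"n_bins must be >= 2, got {n_bins}")
    classes = ds.classes
    label_pos = {c: i for i, c in enumerate(classes)}
    cy = np.array([label_pos[v] for v in ds.y])
    scores = np.zeros(ds.n_features)
    for j in range(ds.n_features):
        x = ds.X[:, j]
        if np.ptp(x) == 0.0:
            continue
        cx = _equal_frequency_codes(x, n_bins)
        scores[j] = max(_plugin_mi_bits(cx, cy), 0.0)
    return _make_ranking(ds.feature_ids, scores, "mi")


# ---------------------------------------------------------------------------
# Relief family
# ---------------------------------------------------------------------------

def _range_normalize(X: np.ndarray) -> np.ndarray:
    mn = X.min(axis=0)
    rng = np.ptp(X, axis=0)
    safe = np.where(rng == 0.0, 1.0, rng)
    return (X - mn) / safe  # constant columns become all-zero


def _relief_setup(ds: Dataset):
    if len(ds.classes) < 2:
        raise DataError("relief scoring requires at least 2 classes")
    Xn = _range_normalize(ds.X)
    D = squareform(pdist(Xn, metric="cityblock"))
    classes = ds.classes
    label_pos = {c: i for i, c in enumerate(classes)}
    cy = np.array([label_pos[v] for v in ds.y])
    idx_by_class = [np.flatnonzero(cy == c) for c in range(len(classes))]
    priors = np.array([len(ix) for ix in idx_by_class], dtype=float) / ds.n_samples
    return Xn, D, cy, idx_by_class, priors


def relieff_scores(ds: Dataset, n_neighbors: int = 20) -> FeatureRanking:
    """Multi-class ReliefF weights.

    For every instance, the ``n_neighbors`` nearest same-class hits pull each
    feature's weight down by the mean feature difference, and per other class
    the nearest misses push it up, weighted by P(class)/(1 - P(own class)).
    Distances are Manhattan on range-normalized features; all n instances are
    visited.  If a class has fewer members than ``n_neighbors`` the count is
    clamped for that class (with a warning).  Weights lie in [-1, 1].
    """
    if n_neighbors < 1:
        raise DataError(f"n_neighbors must be positive, got {n_neighbors}")
    Xn, D, cy, idx_by_class, priors = _relief_setup(ds)
    n, p = Xn.shape
    smallest = min(len(ix) for ix in idx_by_class)
    if smallest - 1 < n_neighbors:
        warnings.warn(
            f"n_neighbors={n_neighbors} exceeds the smallest class "
            f"(size {smallest}); clamping per class",
            stacklevel=2,
        )
    W = np.zeros(p)
    for i in range(n):
        ci = cy[i]
        for c, idx in enumerate(idx_by_class):
            if c == ci:
                cand = idx[idx != i]
            else:
                cand = idx
            k = min(n_neighbors, len(cand))
            if k == 0:
                continue
            d = D[i, cand]
            nb = cand[np.argpartition(d, k - 1)[:k]]
            diff = np.abs(Xn[i] - Xn[nb]).sum(axis=0)
            if c == ci:
                W -= diff / (n * k)
            else:
                W += (priors[c] / (1.0 - priors[ci])) * diff / (n * k)
    return _make_ranking(ds.feature_ids, W, "relieff")


def _surf_weights(ds: Dataset, include_far: bool) -> np.ndarray:
    Xn, D, cy, idx_by_class, priors = _relief_setup(ds)
    n, p = Xn.shape
    if n < 2:
        raise DataError("relief scoring requires at least 2 samples")
    iu = np.triu_indices(n, k=1)
    T = float(D[iu].mean())
    W = np.zeros(p)
    zones = [(lambda d: d < T, 1.0)]
    if include_far:
        zones.append((lambda d: d > T, -1.0))
    for i in range(n):
        ci = cy[i]
        d = D[i]
        for zone, sign in zones:
            inz = zone(d)
            inz[i] = False
            for c, idx in enumerate(idx_by_class):
                nb = idx[inz[idx]]
                if nb.size == 0:
                    continue
                diff = np.abs(Xn[i] - Xn[nb]).sum(axis=0)
                if c == ci:
                    W -= sign * diff / (n * nb.size)
                else:
                    W += sign * (priors[c] / (1.0 - priors[ci])) * diff / (n * nb.size)
    return W


def surf_scores(ds: Dataset) -> FeatureRanking:
    """SURF weights: every instance within the similarity threshold T votes.

    T is the mean over all pairwise instance distances; neighbors are the
    instances at distance strictly below T (an instance exactly at T joins
    neither zone).  Hits and prior-weighted misses update weights as in
    ReliefF, normalized by the realized neighbor counts.
    """
    return _make_ranking(ds.feature_ids, _surf_weights(ds, include_far=False), "surf")


def surfstar_scores(ds: Dataset) -> FeatureRanking:
    """SURF* weights: the near zone scores as SURF, the far zone with
    inverted sign (far hits push weights up, far misses down)."""
    return _make_ranking(
        ds.feature_ids, _surf_weights(ds, include_far=True), "surfstar"
    )
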