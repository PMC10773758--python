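"""The Gini-importance feature combinator (GINI-Select) and its CART substrate.

The third selection stage reconciles the four stage-2 subsets S1..S4 (each of
size k).  Features chosen by all four filters form the intersection F0 and are
kept outright.  The remaining candidates D = (S1 u S2 u S3 u S4) \\ F0 are
ranked by CART Gini importance — a single deterministic classification tree is
grown on the training data restricted to D, and each feature accumulates the
impurity reduction of the nodes it splits — and the top k - |F0| are appended
so the final subset always has exactly k features.

Gini impurity of a label multiset: Gini(D) = 1 - sum_k P_k^2.  A split of D
into D1/D2 by (feature j, threshold t) scores
Gini(D, j) = |D1|/|D| Gini(D1) + |D2|/|D| Gini(D2), and its purity boost is
Gain(j) = Gini(D) - Gini(D, j).  Importances are normalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import DataError, Dataset
from .filters import FeatureRanking

__all__ = [
    "gini_impurity",
    "split_gini",
    "CARTNode",
    "CARTTree",
    "build_cart",
    "gini_importance",
    "gini_select",
    "SelectionResult",
]

# a candidate split must beat the incumbent by more than this to replace it;
# keeps tie-breaking (lowest feature index, then lowest threshold) robust to
# float noise in mathematically equal gains
GAIN_TOL = 1e-12


def gini_impurity(labels) -> float:
    """1 - sum of squared class proportions of a non-empty label multiset."""
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise DataError("gini_impurity of an empty multiset is undefined")
    _, counts = np.unique(labels.astype(str), return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p**2))


def split_gini(node_labels, feature_values, threshold: float) -> float:
    """Size-weighted impurity after splitting at ``threshold`` (<= goes left)."""
    labels = np.asarray(node_labels, dtype=object)
    values = np.asarray(feature_values, dtype=float)
    if labels.shape != values.shape:
        raise DataError("labels and values length mismatch")
    left = values <= threshold
    n_l = int(left.sum())
    if n_l == 0 or n_l == len(values):
        raise DataError(f"degenerate split at threshold {threshold}")
    n = len(values)
    return (
        n_l / n * gini_impurity(labels[left])
        + (n - n_l) / n * gini_impurity(labels[~left])
    )


@dataclass
class CARTNode:
    indices: np.ndarray              # sample indices (into the tree's dataset)
    gini: float
    node_fraction: float             # |node| / n_total
    split_feature: int | None = None  # column index within the tree's features
    split_feature_id: str | None = None
    split_threshold: float | None = None
    gain: float = 0.0
    left: "CARTNode | None" = None
    right: "CARTNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


@dataclass
class CARTTree:
    root: CARTNode
    feature_ids: list[str]
    n_samples: int

    def internal_nodes(self):
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                yield node
                stack.append(node.right)
                stack.append(node.left)

    def structure(self) -> list[tuple[str, float]]:
        """Preorder list of (split feature id, threshold) — a shape fingerprint."""
        out = []

        def walk(node):
            if node.is_leaf:
                out.append(("leaf", float("nan")))
            else:
                out.append((node.split_feature_id, node.split_threshold))
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out


def _best_split(X: np.ndarray, yc: np.ndarray, idx: np.ndarray, C: int,
                parent_gini: float):
    """Best (feature, threshold) over midpoints of consecutive distinct values.

    Returns (gain, feature, threshold) or None.  Features are scanned in
    ascending column order and thresholds ascending; a candidate replaces the
    incumbent only when its gain exceeds it by more than GAIN_TOL, so the
    earliest candidate wins among (near-)ties.
    """
    n = len(idx)
    yn = yc[idx]
    best = None  # (gain, feature, threshold)
    for j in range(X.shape[1]):
        v = X[idx, j]
        order = np.argsort(v, kind="stable")
        vs = v[order]
        if vs[0] == vs[-1]:
            continue
        ys = yn[order]
        onehot = np.zeros((n, C))
        onehot[np.arange(n), ys] = 1.0
        cum = onehot.cumsum(axis=0)
        valid = vs[:-1] < vs[1:]
        if not valid.any():
            continue
        n_l = np.arange(1, n)[valid].astype(float)
        lcnt = cum[:-1][valid]
        total = cum[-1]
        rcnt = total - lcnt
        n_r = n - n_l
        g_l = 1.0 - ((lcnt / n_l[:, None]) ** 2).sum(axis=1)
        g_r = 1.0 - ((rcnt / n_r[:, None]) ** 2).sum(axis=1)
        gains = parent_gini - (n_l * g_l + n_r * g_r) / n
        gmax = gains.max()
        pos = int(np.flatnonzero(gains >= gmax - GAIN_TOL)[0])  # lowest threshold
        gain = float(gains[pos])
        thr = float((vs[:-1][valid][pos] + vs[1:][valid][pos]) / 2.0)
        if best is None or gain > best[0] + GAIN_TOL:
            best = (gain, j, thr)
    return best


def build_cart(ds: Dataset, min_samples_split: int = 2) -> CARTTree:
    """Grow a single deterministic CART classification tree.

    At each node the (feature, threshold) pair maximizing the Gini gain over
    midpoints of consecutive distinct sorted values is chosen ("<= threshold"
    goes left); growth stops on pure nodes, nodes smaller than
    ``min_samples_split``, or when no split improves impurity.  No pruning,
    no feature subsampling.
    """
    if ds.n_samples < 1 or ds.n_features < 1:
        raise DataError("build_cart needs at least one sample and one feature")
    classes = ds.classes
    label_pos = {c: i for i, c in enumerate(classes)}
    yc = np.array([label_pos[v] for v in ds.y])
    C = len(classes)
    n_total = ds.n_samples

    def node_gini(idx):
        counts = np.bincount(yc[idx], minlength=C)
        p = counts / len(idx)
        return float(1.0 - np.sum(p**2))

    def grow(idx: np.ndarray) -> CARTNode:
        g = node_gini(idx)
        node = CARTNode(indices=idx, gini=g, node_fraction=len(idx) / n_total)
        if g == 0.0 or len(idx) < min_samples_split:
            return node
        found = _best_split(ds.X, yc, idx, C, g)
        if found is None or found[0] <= GAIN_TOL:
            return node
        gain, j, thr = found
        left = idx[ds.X[idx, j] <= thr]
        right = idx[ds.X[idx, j] > thr]
        node.split_feature = j
        node.split_feature_id = ds.feature_ids[j]
        node.split_threshold = thr
        node.gain = gain
        node.left = grow(left)
        node.right = grow(right)
        return node

    return CARTTree(grow(np.arange(n_total)), list(ds.feature_ids), n_total)


def gini_importance(
    tree: CARTTree,
    feature_universe: list[str] | None = None,
    weighted: bool = True,
) -> dict[str, float]:
    """Per-feature Gini importance over ``feature_universe``, summing to 1.

    Each internal node contributes its gain — weighted by the fraction of
    samples reaching the node (mean-decrease-impurity) unless
    ``weighted=False``, which accumulates the raw per-node gains — to its
    split feature.  If the tree never split, all importances are 0.
    """
    universe = list(feature_universe) if feature_universe is not None else list(
        tree.feature_ids
    )
    missing = set(tree.feature_ids) - set(universe)
    if missing:
        raise DataError(f"tree features missing from universe: {sorted(missing)}")
    imp = {f: 0.0 for f in universe}
    for node in tree.internal_nodes():
        w = node.node_fraction if weighted else 1.0
        imp[node.split_feature_id] += w * node.gain
    total = sum(imp.values())
    if total > 0.0:
        imp = {f: v / total for f, v in imp.items()}
    return imp


@dataclass
class SelectionResult:
    """Final selected features with per-stage provenance."""

    final_features: list[str]
    intersection_features: list[str]
    gini_added_features: list[str]
    subsets: dict[str, list[str]]          # method name -> stage-2 subset
    candidate_pool: list[str]              # D = union \ intersection
    importances: dict[str, float] | None = None
    stage2_scores: dict[str, dict[str, float]] | None = None
    stage1_pool: list[str] | None = None
    spearman_dropped: list[tuple[str, str, float]] | None = None

    def to_json_dict(self) -> dict:
        return {
            "final_features": self.final_features,
            "intersection_features": self.intersection_features,
            "gini_added_features": self.gini_added_features,
            "subsets": self.subsets,
            "candidate_pool": self.candidate_pool,
            "importances": self.importances,
            "stage2_scores": self.stage2_scores,
            "stage1_pool": self.stage1_pool,
            "spearman_dropped": self.spearman_dropped,
        }


def _mean_rank_order(D: list[str], rankings: list[FeatureRanking], train: Dataset):
    pos = {f: i for i, f in enumerate(train.feature_ids)}
    mean_rank = {
        f: float(np.mean([r.rank_of(f) for r in rankings if f in dict(r.entries)]))
        if any(f in dict(r.entries) for r in rankings)
        else float("inf")
        for f in D
    }
    return sorted(D, key=lambda f: (mean_rank[f], pos[f]))


def gini_select(
    S1: list[str],
    S2: list[str],
    S3: list[str],
    S4: list[str],
    train: Dataset,
    k: int,
    rankings: list[FeatureRanking] | None = None,
    weighted_gain: bool = True,
    min_samples_split: int = 2,
) -> SelectionResult:
    """GINI-Select: intersection first, then top up by CART Gini importance.

    Each subset must hold exactly k unique features of ``train``.  The
    intersection F0 = S1 n S2 n S3 n S4 is retained outright; if |F0| = k it
    is returned without building a tree.  Otherwise a CART tree is grown on
    the training data restricted to D = union \\ F0 and the k - |F0| features
    of highest Gini importance are appended (ties by ascending column index).
    If the tree yields zero total gain, D is instead ordered by mean rank
    across the stage-2 rankings (column order if none are supplied).
    """
    if k <= 0:
        raise DataError(f"k must be positive, got {k}")
    subsets = [list(S) for S in (S1, S2, S3, S4)]
    for i, S in enumerate(subsets, start=1):
        if len(S) != k or len(set(S)) != k:
            raise DataError(f"S{i} must contain exactly {k} unique features")
        unknown = set(S) - set(train.feature_ids)
        if unknown:
            raise DataError(f"S{i} contains unknown features: {sorted(unknown)}")
    inter = set(subsets[0]).intersection(*subsets[1:])
    F0 = [f for f in subsets[0] if f in inter]  # ordered as in S1
    union = set().union(*subsets)
    pos = {f: i for i, f in enumerate(train.feature_ids)}
    D = [f for f in train.feature_ids if f in union and f not in inter]

    if len(F0) == k:
        return SelectionResult(
            final_features=F0,
            intersection_features=F0,
            gini_added_features=[],
            subsets={f"S{i}": S for i, S in enumerate(subsets, start=1)},
            candidate_pool=D,
        )

    tree = build_cart(train.select_features(D), min_samples_split=min_samples_split)
    imp = gini_importance(tree, D, weighted=weighted_gain)
    if sum(imp.values()) > 0.0:
        ordered = sorted(D, key=lambda f: (-imp[f], pos[f]))
    elif rankings:
        ordered = _mean_rank_order(D, rankings, train)
    else:
        ordered = sorted(D, key=lambda f: pos[f])
    added = ordered[: k - len(F0)]
    return SelectionResult(
        final_features=F0 + added,
        intersection_features=F0,
        gini_added_features=added,
        subsets={f"S{i}": S for i, S in enumerate(subsets, start=1)},
        candidate_pool=D,
        importances=imp,
    )
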