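import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from efsgini import (
    DataError,
    Dataset,
    build_cart,
    gini_importance,
    gini_impurity,
    gini_select,
    split_gini,
)

# ---------------------------------------------------------------------------
# independent oracle: greedy tree via exhaustive split enumeration
# ---------------------------------------------------------------------------

TOL = 1e-12


def _oracle_gini(labels):
    _, counts = np.unique(np.asarray(labels, dtype=str), return_counts=True)
    p = counts / len(labels)
    return 1.0 - float((p**2).sum())


def _oracle_tree(X, y, idx=None, min_samples_split=2):
    """Preorder (feature_index, threshold) list by naive enumeration of every
    candidate split, scanning features then thresholds ascending and replacing
    the incumbent only on a > TOL improvement."""
    if idx is None:
        idx = np.arange(len(y))
    out = []

    def grow(node_idx):
        labels = [y[i] for i in node_idx]
        g0 = _oracle_gini(labels)
        best = None
        if g0 > 0.0 and len(node_idx) >= min_samples_split:
            for j in range(X.shape[1]):
                vals = sorted(set(X[node_idx, j]))
                for a, b in zip(vals[:-1], vals[1:]):
                    t = (a + b) / 2.0
                    left = node_idx[X[node_idx, j] <= t]
                    right = node_idx[X[node_idx, j] > t]
                    gain = g0 - (
                        len(left) * _oracle_gini([y[i] for i in left])
                        + len(right) * _oracle_gini([y[i] for i in right])
                    ) / len(node_idx)
                    if best is None or gain > best[0] + TOL:
                        best = (gain, j, t, left, right)
        if best is None or best[0] <= TOL:
            out.append(("leaf", None))
            return
        _, j, t, left, right = best
        out.append((j, t))
        grow(left)
        grow(right)

    grow(idx)
    return out


def _tree_preorder(tree):
    return [
        ("leaf", None) if f == "leaf" else (tree.feature_ids.index(f), t)
        for f, t in tree.structure()
    ]


def _ds(X, y):
    X = np.asarray(X, dtype=float)
    return Dataset(
        X, y, [f"f{j}" for j in range(X.shape[1])],
        [f"s{i}" for i in range(X.shape[0])],
    )


class TestGiniImpurity:
    @pytest.mark.parametrize(
        "labels,expected",
        [
            (["a", "a", "a"], 0.0),
            (["a", "a", "b", "b"], 0.5),
            (["a", "a", "b", "c"], 0.625),
        ],
    )
    def test_known_multisets(self, labels, expected):
        assert gini_impurity(labels) == pytest.approx(expected)

    def test_empty_raises(self):
        with pytest.raises(DataError):
            gini_impurity([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=20))
    def test_bounds_and_permutation_invariance(self, labels):
        g = gini_impurity(labels)
        n_classes = len(set(labels))
        assert 0.0 <= g <= 1.0 - 1.0 / n_classes + 1e-12
        assert gini_impurity(sorted(labels)) == pytest.approx(g)


class TestSplitGini:
    def test_perfect_split_is_zero(self):
        assert split_gini(["a", "a", "b", "b"], [1.0, 2.0, 3.0, 4.0], 2.5) == 0.0

    def test_useless_split_keeps_half(self):
        got = split_gini(["a", "b", "a", "b"], [1.0, 2.0, 3.0, 4.0], 2.5)
        assert got == pytest.approx(0.5)

    def test_degenerate_split_rejected(self):
        with pytest.raises(DataError, match="degenerate"):
            split_gini(["a", "b"], [1.0, 2.0], 5.0)


class TestBuildCart:
    def test_pure_labels_single_leaf(self):
        ds = _ds([[1.0], [2.0], [3.0]], ["a", "a", "a"])
        tree = build_cart(ds)
        assert tree.root.is_leaf and tree.root.gini == 0.0

    def test_1d_separable_depth_one_midpoint(self):
        ds = _ds([[1.0], [2.0], [5.0], [6.0]], ["a", "a", "b", "b"])
        tree = build_cart(ds)
        assert tree.root.split_feature_id == "f0"
        assert tree.root.split_threshold == pytest.approx(3.5)
        assert tree.root.left.is_leaf and tree.root.right.is_leaf

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        p = int(rng.integers(1, 4))
        X = rng.integers(0, 4, size=(n, p)).astype(float)
        y = [str(c) for c in rng.integers(0, 3, size=n)]
        tree = build_cart(_ds(X, y))
        assert _tree_preorder(tree) == _oracle_tree(X, np.array(y))

    def test_gain_positive_at_every_split(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        y = [f"c{i % 3}" for i in range(30)]
        tree = build_cart(_ds(X, y))
        for node in tree.internal_nodes():
            assert node.gain > 0.0
            # children's index sets partition the parent's
            merged = sorted(
                list(node.left.indices) + list(node.right.indices)
            )
            assert merged == sorted(node.indices)


class TestGiniImportance:
    def test_single_leaf_all_zero(self):
        tree = build_cart(_ds([[1.0], [2.0]], ["a", "a"]))
        imp = gini_importance(tree)
        assert all(v == 0.0 for v in imp.values())

    def test_depth_one_importance_is_one(self):
        tree = build_cart(_ds([[1.0, 7.0], [2.0, 7.0], [5.0, 7.0], [6.0, 7.0]],
                              ["a", "a", "b", "b"]))
        imp = gini_importance(tree)
        assert imp["f0"] == pytest.approx(1.0) and imp["f1"] == 0.0

    def test_worked_example_hand_accumulation(self, worked):
        ds, exp = worked
        cart = exp["cart_on_D"]
        tree = build_cart(ds.select_features(cart["feature_ids"]))
        imp = gini_importance(tree)
        for f, v in cart["importances"].items():
            assert imp[f] == pytest.approx(v, abs=1e-9)

    def test_weighted_vs_unweighted_dual_route(self, worked):
        # recompute both variants independently from the tree's own structure
        # using only the public impurity primitives
        ds, exp = worked
        cart = exp["cart_on_D"]
        sub = ds.select_features(cart["feature_ids"])
        tree = build_cart(sub)
        for weighted in (True, False):
            acc = {f: 0.0 for f in cart["feature_ids"]}
            for node in tree.internal_nodes():
                labels = [sub.y[i] for i in node.indices]
                vals = sub.X[node.indices, node.split_feature]
                gain = gini_impurity(labels) - split_gini(
                    labels, vals, node.split_threshold
                )
                w = len(node.indices) / sub.n_samples if weighted else 1.0
                acc[node.split_feature_id] += w * gain
            total = sum(acc.values())
            expected = {f: v / total for f, v in acc.items()}
            got = gini_importance(tree, weighted=weighted)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_normalization_sums_to_one(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = [f"c{i % 2}" for i in range(40)]
        imp = gini_importance(build_cart(_ds(X, y)))
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-12)


def _oracle_gini_select(S1, S2, S3, S4, train, k):
    """Direct transcription of the combinator semantics."""
    inter = [f for f in S1 if f in S2 and f in S3 and f in S4]
    union = set(S1) | set(S2) | set(S3) | set(S4)
    D = [f for f in train.feature_ids if f in union and f not in inter]
    if len(inter) == k:
        return inter
    tree = build_cart(train.select_features(D))
    imp = gini_importance(tree, D)
    pos = {f: i for i, f in enumerate(train.feature_ids)}
    ordered = sorted(D, key=lambda f: (-imp[f], pos[f]))
    return inter + ordered[: k - len(inter)]


class TestGiniSelect:
    def test_identical_subsets_short_circuit(self, worked):
        ds, _ = worked
        S = ["g1", "g3", "g6"]
        res = gini_select(S, S, S, S, ds, 3)
        assert res.final_features == S
        assert res.gini_added_features == []
        assert res.importances is None  # no CART was built

    def test_worked_example_outcome(self, worked):
        ds, exp = worked
        gs = exp["gini_select"]
        res = gini_select(gs["S1"], gs["S2"], gs["S3"], gs["S4"], ds, gs["k"])
        assert res.final_features == gs["final"]
        assert res.intersection_features == gs["intersection"]
        assert res.candidate_pool == gs["candidate_pool"]

    def test_disjoint_subsets_equal_importance_topk(self, worked):
        ds, _ = worked
        S1, S2, S3, S4 = [["g1"], ["g3"], ["g6"], ["g8"]]
        res = gini_select(S1, S2, S3, S4, ds, 1)
        assert res.intersection_features == []
        assert res.final_features == _oracle_gini_select(S1, S2, S3, S4, ds, 1)

    @pytest.mark.parametrize("seed", range(15))
    def test_invariants_random_configurations(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 16, 10
        X = rng.normal(size=(n, p))
        y = [str(c) for c in rng.integers(0, 2, size=n)]
        train = _ds(X, y)
        k = int(rng.integers(1, 5))
        subsets = [
            [f"f{j}" for j in rng.choice(p, size=k, replace=False)]
            for _ in range(4)
        ]
        res = gini_select(*subsets, train, k)
        union = set().union(*map(set, subsets))
        inter = set(subsets[0]).intersection(*map(set, subsets[1:]))
        assert len(res.final_features) == k
        assert len(set(res.final_features)) == k
        assert inter <= set(res.final_features)
        assert set(res.final_features) <= union
        assert res.final_features == _oracle_gini_select(*subsets, train, k)

    def test_zero_gain_falls_back_to_column_order(self):
        # candidate features are all constant: the tree cannot split, so the
        # top-up falls back to a deterministic ordering
        X = np.column_stack([
            [1.0, 2.0, 3.0, 4.0],   # f0 informative (in all subsets)
            [5.0, 5.0, 5.0, 5.0],
            [7.0, 7.0, 7.0, 7.0],
            [9.0, 9.0, 9.0, 9.0],
            [3.0, 3.0, 3.0, 3.0],
        ])
        train = _ds(X, ["a", "a", "b", "b"])
        res = gini_select(
            ["f0", "f1"], ["f0", "f2"], ["f0", "f3"], ["f0", "f4"], train, 2
        )
        assert res.final_features == ["f0", "f1"]

    def test_wrong_subset_size_rejected(self, worked):
        ds, _ = worked
        with pytest.raises(DataError, match="exactly"):
            gini_select(["g1"], ["g1", "g3"], ["g1", "g3"], ["g1", "g3"], ds, 2)

    def test_k_zero_rejected(self, worked):
        ds, _ = worked
        with pytest.raises(DataError, match="positive"):
            gini_select([], [], [], [], ds, 0)
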