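"""Leaf-wise boosting engine against exhaustive split-search oracles."""

import numpy as np
import pytest

from cropboost import gbdt

from oracles import oracle_best_split, oracle_split_gain


def walk_splits(tree):
    """(feature, threshold, gain) of every internal node, root-first."""
    out = []
    for node in tree.nodes:
        if not node.is_leaf:
            out.append((node.feature, node.threshold, node.gain))
    return out


class TestSingleTree:
    def test_constant_target_no_splits(self):
        X = np.random.default_rng(0).integers(0, 3, (30, 4)).astype(float)
        m = gbdt.fit(X, np.full(30, 3.5), n_iterations=5,
                     min_samples_leaf=1)
        assert all(len(t.nodes) == 1 for t in m.trees)
        assert (m.feature_gain == 0).all()
        np.testing.assert_allclose(gbdt.predict(m, X), 3.5)

    def test_separable_feature_recovers_group_means(self):
        """One binary feature determines y; lam=0, lr=1, one 2-leaf tree
        reproduces the group means exactly (closed-form leaf values)."""
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, 40).astype(float)
        y = np.where(x == 0, 2.0, 5.0)
        X = np.column_stack([x, rng.integers(0, 3, 40).astype(float)])
        m = gbdt.fit(X, y, n_iterations=1, learning_rate=1.0,
                     lambda_l2=0.0, max_leaves=2, min_samples_leaf=1)
        np.testing.assert_allclose(gbdt.predict(m, X), y, atol=1e-12)

    def test_second_split_lands_on_best_gain_leaf(self):
        """Constructed so f0 splits first and f1 refines the *left* child;
        the engine must split the left leaf, not the right."""
        # left branch (f0=0): y split by f1 into -4/ +4; right branch: y=10
        X = np.array([[0, 0], [0, 0], [0, 1], [0, 1],
                      [1, 0], [1, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([-4.0, -4.0, 4.0, 4.0, 10.0, 10.0, 10.0, 10.0])
        m = gbdt.fit(X, y, n_iterations=1, learning_rate=1.0,
                     lambda_l2=0.0, max_leaves=3, min_samples_leaf=1)
        tree = m.trees[0]
        root = tree.nodes[0]
        assert root.feature == 0
        left, right = tree.nodes[root.left], tree.nodes[root.right]
        assert not left.is_leaf and left.feature == 1
        assert right.is_leaf
        np.testing.assert_allclose(gbdt.predict(m, X), y, atol=1e-12)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(30))
    def test_every_split_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 51))
        p = int(rng.integers(1, 6))
        X = rng.integers(0, int(rng.integers(2, 10)), (n, p)).astype(float)
        if seed % 3 == 0:  # sprinkle missing values
            X[rng.random((n, p)) < 0.1] = np.nan
        y = rng.normal(size=n)
        msl = int(rng.integers(1, 4))
        m = gbdt.fit(X, y, n_iterations=1, max_leaves=4,
                     min_samples_leaf=msl, lambda_l2=1.0)
        tree = m.trees[0]
        g = np.full(n, y.mean()) - y       # first-iteration l2 gradients
        h = np.ones(n)
        # replay growth: check each internal node's split versus the oracle
        stack = [(0, np.arange(n))]
        while stack:
            nid, idx = stack.pop()
            node = tree.nodes[nid]
            if node.is_leaf:
                continue
            gain, f, thr, miss_left = oracle_best_split(
                X, g, h, idx.tolist(), 1.0, msl)
            assert node.gain == pytest.approx(gain, abs=1e-9)
            if (node.feature, node.threshold) == (f, thr):
                assert node.missing_direction == \
                    ("left" if miss_left else "right")
            else:
                # exact gain tie (duplicated partition): the engine's
                # choice must itself be an optimal split
                chosen = oracle_split_gain(X, g, h, idx.tolist(),
                                           node.feature, node.threshold,
                                           1.0, msl)
                assert chosen == pytest.approx(gain, abs=1e-9)
            col = X[idx, node.feature]
            miss = np.isnan(col)
            goleft = np.where(miss, node.missing_direction == "left",
                              col <= node.threshold)
            stack.append((node.left, idx[goleft]))
            stack.append((node.right, idx[~goleft]))


class TestInvariances:
    def test_monotone_recoding_bit_identical(self):
        """Strictly monotone per-feature transforms leave predictions
        bit-identical (increasing or decreasing)."""
        rng = np.random.default_rng(10)
        X = rng.integers(0, 3, (120, 8)).astype(float)
        y = X[:, 0] - 2 * X[:, 3] + rng.normal(0, 0.5, 120)
        m = gbdt.fit(X, y, n_iterations=20, min_samples_leaf=2)
        base = gbdt.predict(m, X)
        inc = {0: 0.0, 1: 3.0, 2: 9.0}
        dec = {0: 4.0, 1: 1.0, 2: 0.0}
        X2 = X.copy()
        for j in range(8):
            table = inc if j % 2 == 0 else dec
            X2[:, j] = np.vectorize(table.get)(X[:, j])
        m2 = gbdt.fit(X2, y, n_iterations=20, min_samples_leaf=2)
        assert np.array_equal(base, gbdt.predict(m2, X2))

    def test_training_loss_non_increasing(self):
        rng = np.random.default_rng(11)
        X = rng.integers(0, 3, (100, 10)).astype(float)
        y = X @ rng.normal(size=10) + rng.normal(0, 0.5, 100)
        m = gbdt.fit(X, y, n_iterations=25, min_samples_leaf=5)
        losses = [gbdt.training_loss(m, X, y, upto=i) for i in range(26)]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_binary_loss_non_increasing_and_probability_range(self):
        rng = np.random.default_rng(12)
        X = rng.integers(0, 3, (100, 6)).astype(float)
        y = (X[:, 0] + rng.normal(0, 0.8, 100) > 1).astype(int)
        m = gbdt.fit(X, y, objective="binary", n_iterations=20,
                     min_samples_leaf=5)
        losses = [gbdt.training_loss(m, X, y, upto=i) for i in range(21)]
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
        p = gbdt.predict(m, X)
        assert ((p > 0) & (p < 1)).all()

    def test_multiclass_probabilities_sum_to_one(self):
        rng = np.random.default_rng(13)
        X = rng.integers(0, 3, (90, 6)).astype(float)
        y = np.array(["low", "mid", "high"])[rng.integers(0, 3, 90)]
        m = gbdt.fit(X, y, objective="multiclass", n_iterations=8,
                     min_samples_leaf=5)
        P = gbdt.predict(m, X)
        assert P.shape == (90, 3)
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)

    def test_serialisation_round_trip(self):
        rng = np.random.default_rng(14)
        X = rng.integers(0, 3, (60, 5)).astype(float)
        y = X[:, 1] + rng.normal(0, 0.3, 60)
        m = gbdt.fit(X, y, n_iterations=5, min_samples_leaf=2)
        m2 = gbdt.BoostedModel.from_json(m.to_json())
        np.testing.assert_array_equal(gbdt.predict(m, X),
                                      gbdt.predict(m2, X))


class TestImportance:
    def test_zero_split_model_all_zeros(self):
        X = np.zeros((20, 3))
        m = gbdt.fit(X, np.random.default_rng(0).normal(size=20),
                     n_iterations=3)
        imp = gbdt.feature_importance(m)
        assert (imp.total_gain == 0).all()
        assert (imp.split_count == 0).all()

    def test_single_split_model(self):
        X = np.array([[0.0], [0.0], [1.0], [1.0]] * 5)
        y = np.tile([0.0, 0.0, 1.0, 1.0], 5)
        m = gbdt.fit(X, y, n_iterations=1, max_leaves=2, min_samples_leaf=1)
        imp = gbdt.feature_importance(m)
        assert imp.split_count.tolist() == [1]
        assert imp.total_gain[0] > 0

    def test_split_count_equals_internal_nodes(self):
        rng = np.random.default_rng(15)
        X = rng.integers(0, 3, (80, 6)).astype(float)
        y = X @ rng.normal(size=6) + rng.normal(0, 0.2, 80)
        m = gbdt.fit(X, y, n_iterations=10, min_samples_leaf=3)
        n_internal = sum(
            1 for t in m.trees for nd in t.nodes if not nd.is_leaf)
        assert int(m.feature_split_count.sum()) == n_internal

    def test_planted_qtl_has_max_gain(self, small_pop):
        from cropboost import geno, simpop
        enc = geno.encode_additive(small_pop.f1)
        truth = small_pop.truth
        # strongest additive QTL should dominate importance
        y = np.asarray(small_pop.phenotypes.values[:, 0])
        m = gbdt.fit(enc, y, n_iterations=50, min_samples_leaf=10)
        imp = gbdt.feature_importance(m)
        top = imp.top(3)
        assert set(top) & set(truth["qtl_idx"])


class TestGridSearch:
    def test_one_point_grid(self):
        rng = np.random.default_rng(16)
        X = rng.integers(0, 3, (40, 4)).astype(float)
        y = X[:, 0] + rng.normal(0, 0.1, 40)
        best, table = gbdt.grid_search(
            X, y, {"n_iterations": [5]}, cv_folds=2, seed=0)
        assert best == {"n_iterations": 5}
        assert len(table) == 1

    def test_known_good_setting_wins(self):
        rng = np.random.default_rng(17)
        X = rng.integers(0, 3, (80, 4)).astype(float)
        y = 2.0 * X[:, 0] + rng.normal(0, 0.1, 80)
        # min_samples_leaf larger than any fold forbids splitting entirely,
        # so the setting that can split must win
        grid = {"min_samples_leaf": [200, 2], "n_iterations": [20]}
        best, table = gbdt.grid_search(X, y, grid, cv_folds=3, seed=1)
        assert best["min_samples_leaf"] == 2
        assert table[0][1] == 0.0  # constant predictions score r = 0

    def test_determinism(self):
        rng = np.random.default_rng(18)
        X = rng.integers(0, 3, (40, 4)).astype(float)
        y = rng.normal(size=40)
        a = gbdt.grid_search(X, y, {"n_iterations": [2, 5]}, 2, seed=7)
        b = gbdt.grid_search(X, y, {"n_iterations": [2, 5]}, 2, seed=7)
        assert a == b

    def test_errors(self):
        X = np.zeros((10, 2))
        y = np.zeros(10)
        with pytest.raises(ValueError, match="empty"):
            gbdt.grid_search(X, y, {}, 2)
        with pytest.raises(ValueError, match="folds"):
            gbdt.grid_search(X, y, {"n_iterations": [1]}, 1)


def test_fit_input_validation():
    X = np.zeros((10, 2))
    with pytest.raises(ValueError, match="non-finite"):
        gbdt.fit(X, np.full(10, np.inf))
    with pytest.raises(ValueError, match="max_leaves"):
        gbdt.fit(X, np.zeros(10), max_leaves=1)
    m = gbdt.fit(X, np.zeros(10), n_iterations=1)
    with pytest.raises(ValueError, match="feature count"):
        gbdt.predict(m, np.zeros((5, 3)))
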