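import numpy as np
import pytest

from rfctsr.forest import (BasisSpec, SplitParams, LeafModel, ForestConfig,
                           TreeNode, basis_expand, fit_leaf_model,
                           split_response, node_purity, split_quality,
                           grow_tree, train_forest, predict_patch,
                           predict_batch, RegressionForest, REJECTED,
                           forest_to_arrays, forest_from_arrays,
                           _draw_candidates)


LINEAR = BasisSpec("linear", 1, True)


class TestBasisExpand:
    def test_linear_with_constant(self):
        np.testing.assert_array_equal(basis_expand([2.0, 3.0], LINEAR),
                                      [1.0, 2.0, 3.0])

    def test_polynomial_elementwise_powers(self):
        np.testing.assert_array_equal(
            basis_expand([2.0], BasisSpec("polynomial", 2)), [1.0, 2.0, 4.0])

    def test_constant_only_degenerate_basis(self):
        np.testing.assert_array_equal(
            basis_expand([5.0, -1.0], BasisSpec("linear", 0)), [1.0])

    def test_matrix_expansion_matches_rowwise(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        basis = BasisSpec("polynomial", 3)
        out = basis_expand(X, basis)
        for i in range(5):
            np.testing.assert_allclose(out[i], basis_expand(X[i], basis))


class TestLeafModel:
    def test_exact_recovery_limit(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(2, 4))  # targets x expanded basis
        X_L = rng.normal(size=(50, 3))
        X_H = basis_expand(X_L, LINEAR) @ A.T
        leaf = fit_leaf_model(X_L, X_H, LINEAR, ridge=1e-12)
        np.testing.assert_allclose(leaf.W, A, atol=1e-8)

    def test_infinite_shrinkage_limit(self):
        rng = np.random.default_rng(2)
        leaf = fit_leaf_model(rng.normal(size=(30, 3)),
                              rng.normal(size=(30, 2)), LINEAR, ridge=1e12)
        assert np.abs(leaf.W).max() < 1e-6

    def test_normal_equations_residual(self):
        # the ridge solution must satisfy (Psi'Psi + eta I) W' = Psi' X_H
        rng = np.random.default_rng(3)
        X_L = rng.normal(size=(20, 3))
        X_H = rng.normal(size=(20, 2))
        eta = 0.37
        leaf = fit_leaf_model(X_L, X_H, LINEAR, ridge=eta)
        Psi = basis_expand(X_L, LINEAR)
        resid = (Psi.T @ Psi + eta * np.eye(4)) @ leaf.W.T - Psi.T @ X_H
        assert np.abs(resid).max() < 1e-6

    def test_matches_reference_ridge_solver(self):
        # independent oracle: scikit-learn Ridge on the expanded basis
        from sklearn.linear_model import Ridge

        rng = np.random.default_rng(4)
        X_L = rng.normal(size=(20, 3))
        X_H = rng.normal(size=(20, 2))
        eta = 0.5
        leaf = fit_leaf_model(X_L, X_H, LINEAR, ridge=eta)
        ref = Ridge(alpha=eta, fit_intercept=False, solver="cholesky")
        ref.fit(basis_expand(X_L, LINEAR), X_H)
        np.testing.assert_allclose(leaf.W, ref.coef_, atol=1e-6)


class TestSplitResponse:
    def test_equality_routes_right(self):
        assert split_response(np.array([5.0]), SplitParams(0, 5.0)) == 1

    def test_below_threshold_routes_left(self):
        assert split_response(np.array([4.9]), SplitParams(0, 5.0)) == 0

    def test_pairwise_form_hand_evaluation(self):
        # r = x[0] - x[1] - 1 = 3 - 1 - 1 = 1 >= 0 -> 1
        assert split_response(np.array([3.0, 1.0]),
                              SplitParams(0, 1.0, second_feature_index=1)) == 1

    def test_index_out_of_range(self):
        with pytest.raises(IndexError):
            split_response(np.array([1.0]), SplitParams(3, 0.0))


class TestNodePurity:
    def test_identical_perfectly_fit_samples(self):
        X_L = np.ones((5, 2))
        X_H = np.full((5, 1), 3.0)
        assert node_purity(X_L, X_H, k=1.0, basis=LINEAR, ridge=1e-8) \
            == pytest.approx(0.0, abs=1e-10)

    def test_k_zero_is_pure_label_residual(self):
        rng = np.random.default_rng(5)
        X_L = rng.normal(size=(10, 2))
        X_H = rng.normal(size=(10, 1))
        model = fit_leaf_model(X_L, X_H, LINEAR, 0.1)
        expected = np.mean(np.sum((X_H - model.predict(X_L, LINEAR)) ** 2,
                                  axis=1))
        assert node_purity(X_L, X_H, 0.0, LINEAR, 0.1, model=model) \
            == pytest.approx(expected, abs=1e-12)

    def test_term_by_term_arithmetic_oracle(self):
        # 3 hand-chosen 1-D samples against a fixed leaf model W = [[0, 1]]
        X_L = np.array([[1.0], [2.0], [4.0]])
        X_H = np.array([[1.5], [1.5], [4.5]])
        model = LeafModel(W=np.array([[0.0, 1.0]]), n_train=3)  # m(x) = x
        # residuals: 0.5^2, 0.5^2, 0.5^2 ; mean x = 7/3
        # scatter: (1-7/3)^2 + (2-7/3)^2 + (4-7/3)^2 = 16/9+1/9+25/9 = 42/9
        k = 2.0
        expected = (0.25 * 3) / 3 + k * (42.0 / 9.0) / 3
        assert node_purity(X_L, X_H, k, LINEAR, 0.1, model=model) \
            == pytest.approx(expected, abs=1e-10)

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError):
            node_purity(np.empty((0, 2)), np.empty((0, 1)), 1.0, LINEAR, 0.1)


class TestSplitQuality:
    def test_separable_clusters(self):
        # two well-separated clusters, each internally constant in both
        # feature and label space: the separating split has zero quality
        X_L = np.vstack([np.zeros((5, 1)), np.full((5, 1), 10.0)])
        X_H = np.vstack([np.full((5, 1), -1.0), np.full((5, 1), 1.0)])
        sep = split_quality(SplitParams(0, 5.0), X_L, X_H, 1.0, LINEAR, 0.1)
        assert sep == pytest.approx(0.0, abs=1e-9)

    def test_mixing_split_scores_worse_than_separating(self):
        # four feature levels, labels -1,-1,+1,+1: the label-respecting
        # threshold beats one that mixes the label clusters in a child
        X_L = np.repeat([0.0, 10.0, 20.0, 30.0], 5)[:, None]
        X_H = np.repeat([-1.0, -1.0, 1.0, 1.0], 5)[:, None]
        sep = split_quality(SplitParams(0, 15.0), X_L, X_H, 1.0, LINEAR, 0.1)
        mix = split_quality(SplitParams(0, 25.0), X_L, X_H, 1.0, LINEAR, 0.1)
        assert 0.0 < sep < mix

    def test_inadmissible_split_returns_sentinel(self):
        X_L = np.arange(10.0)[:, None]
        X_H = np.ones((10, 1))
        q = split_quality(SplitParams(0, -100.0), X_L, X_H, 1.0, LINEAR, 0.1,
                          min_leaf_samples=2)
        assert q == REJECTED

    def test_matches_exhaustive_enumeration(self):
        # brute-force oracle: for each threshold, form the two children and
        # accumulate n_c * E_c with the node-mean predictor, term by term
        rng = np.random.default_rng(6)
        X_L = rng.normal(size=(10, 1))
        X_H = rng.normal(size=(10, 2))
        k = 1.3
        for thr in np.linspace(-2, 2, 21):
            theta = SplitParams(0, float(thr))
            got = split_quality(theta, X_L, X_H, k, LINEAR, 0.1,
                                min_leaf_samples=1)
            right = X_L[:, 0] >= thr
            if min(right.sum(), (~right).sum()) < 1:
                assert got == REJECTED
                continue
            expected = 0.0
            for mask in (~right, right):
                H, L = X_H[mask], X_L[mask]
                e = (np.sum((H - H.mean(0)) ** 2, axis=1).mean()
                     + k * np.sum((L - L.mean(0)) ** 2, axis=1).mean())
                expected += mask.sum() * e
            assert got == pytest.approx(expected, rel=1e-10)


class TestGrowTree:
    def _piecewise_data(self, n=300, seed=7):
        rng = np.random.default_rng(seed)
        x = rng.uniform(-2, 2, size=(n, 1))
        y = np.where(x < 0, -1.0, 1.0)
        return x, y

    def test_depth_zero_single_global_leaf(self):
        X_L, X_H = self._piecewise_data()
        cfg = ForestConfig(max_depth=0, min_leaf_samples=5)
        tree = grow_tree((X_L, X_H), cfg, LINEAR, rng_seed=0)
        assert tree.is_leaf
        ref = fit_leaf_model(X_L, X_H, LINEAR, cfg.ridge)
        np.testing.assert_allclose(tree.leaf.W, ref.W)

    def test_piecewise_structure_recovered(self):
        X_L, X_H = self._piecewise_data()
        cfg = ForestConfig(max_depth=1, min_leaf_samples=5,
                           n_candidate_splits=60)
        basis = BasisSpec("linear", 0)  # constant-only leaves
        tree = grow_tree((X_L, X_H), cfg, basis, rng_seed=1)
        assert not tree.is_leaf
        gap_lo = X_L[X_L < 0].max()
        gap_hi = X_L[X_L >= 0].min()
        assert gap_lo <= tree.split.threshold <= gap_hi
        left = tree.left.leaf.W.ravel()[0]
        right = tree.right.leaf.W.ravel()[0]
        assert left == pytest.approx(-1.0, abs=0.05)
        assert right == pytest.approx(1.0, abs=0.05)

    def test_structural_invariants(self):
        rng = np.random.default_rng(8)
        X_L = rng.normal(size=(400, 4))
        X_H = rng.normal(size=(400, 2))
        cfg = ForestConfig(max_depth=4, min_leaf_samples=20)
        tree = grow_tree((X_L, X_H), cfg, LINEAR, rng_seed=3)

        def walk(node):
            assert node.depth <= cfg.max_depth
            if node.is_leaf:
                assert node.leaf.n_train >= cfg.min_leaf_samples
                assert np.all(np.isfinite(node.leaf.W))
            else:
                walk(node.left)
                walk(node.right)
        walk(tree)

    def test_root_split_attains_candidate_minimum(self):
        # re-score the exact candidate set the tree drew; the chosen root
        # split must attain the minimum quality over it
        rng_seed = 11
        rng = np.random.default_rng(9)
        X_L = rng.normal(size=(150, 1))
        X_H = np.sin(2 * X_L) + 0.1 * rng.normal(size=(150, 1))
        cfg = ForestConfig(max_depth=3, min_leaf_samples=10)
        tree = grow_tree((X_L, X_H), cfg, LINEAR, rng_seed=rng_seed)
        assert not tree.is_leaf
        cands = _draw_candidates(X_L, np.random.default_rng(rng_seed), cfg)
        scores = [split_quality(th, X_L, X_H, cfg.split_reg, LINEAR,
                                cfg.ridge, cfg.min_leaf_samples)
                  for th in cands]
        best = min(s for s in scores if np.isfinite(s))
        chosen = split_quality(tree.split, X_L, X_H, cfg.split_reg, LINEAR,
                               cfg.ridge, cfg.min_leaf_samples)
        assert chosen == pytest.approx(best, rel=1e-10)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            grow_tree((np.zeros((3, 2)), np.zeros((3, 1))),
                      ForestConfig(min_leaf_samples=10), LINEAR, 0)


class TestForest:
    def test_single_tree_forest_equals_tree_prediction(self):
        rng = np.random.default_rng(10)
        X_L = rng.normal(size=(200, 3))
        X_H = rng.normal(size=(200, 2))
        cfg = ForestConfig(n_trees=1, max_depth=3, min_leaf_samples=20, seed=5)
        forest = train_forest((X_L, X_H), cfg, LINEAR)
        x = rng.normal(size=3)
        single = np.zeros((1, 2))
        from rfctsr.forest import _tree_predict, basis_expand as be
        _tree_predict(forest.trees[0], x[None, :], be(x[None, :], LINEAR),
                      np.array([0]), single)
        np.testing.assert_allclose(predict_patch(forest, x), single[0])

    def test_seed_determinism(self):
        rng = np.random.default_rng(11)
        X_L = rng.normal(size=(200, 3))
        X_H = rng.normal(size=(200, 2))
        cfg = ForestConfig(n_trees=3, max_depth=3, min_leaf_samples=20, seed=9)
        f1 = train_forest((X_L, X_H), cfg, LINEAR)
        f2 = train_forest((X_L, X_H), cfg, LINEAR)
        X = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(predict_batch(f1, X),
                                      predict_batch(f2, X))

    def test_default_tree_count(self):
        assert ForestConfig().n_trees == 10

    def test_hand_built_two_tree_average(self):
        a = np.array([[1.0, 0.0], [2.0, 0.0]])  # predicts [1, 2] constants
        b = np.array([[3.0, 0.0], [6.0, 0.0]])  # predicts [3, 6]
        trees = [TreeNode(depth=0, leaf=LeafModel(W=a, n_train=1)),
                 TreeNode(depth=0, leaf=LeafModel(W=b, n_train=1))]
        forest = RegressionForest(trees=trees, basis=LINEAR,
                                  config=ForestConfig(n_trees=2),
                                  n_features=1, n_targets=2)
        np.testing.assert_allclose(predict_patch(forest, np.array([0.0])),
                                   [2.0, 4.0])

    def test_leaf_prediction_linear_in_basis(self):
        W = np.array([[0.5, 2.0]])
        leaf = LeafModel(W=W, n_train=1)
        x = np.array([3.0])
        p1 = leaf.predict(x[None, :], LINEAR)[0]
        p2 = leaf.predict(2 * x[None, :], LINEAR)[0]
        np.testing.assert_allclose(p1, W @ np.array([1.0, 3.0]))
        np.testing.assert_allclose(p2, W @ np.array([1.0, 6.0]))

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(12)
        cfg = ForestConfig(n_trees=1, max_depth=1, min_leaf_samples=10)
        forest = train_forest((rng.normal(size=(50, 3)),
                               rng.normal(size=(50, 1))), cfg, LINEAR)
        with pytest.raises(ValueError):
            predict_patch(forest, np.zeros(5))


class TestParameterRecovery:
    def test_depth_zero_rmse_halves_when_n_quadruples(self):
        # planted global linear regime x_H = A Psi(x_L) + noise: the ridge
        # estimate's Frobenius error should scale ~ 1/sqrt(N)
        def rmse(n, seed):
            rng = np.random.default_rng(seed)
            A = rng.normal(size=(2, 4))
            X_L = rng.normal(size=(n, 3))
            X_H = basis_expand(X_L, LINEAR) @ A.T \
                + 0.5 * rng.normal(size=(n, 2))
            cfg = ForestConfig(n_trees=1, max_depth=0, min_leaf_samples=5,
                               ridge=1e-6, seed=seed)
            forest = train_forest((X_L, X_H), cfg, LINEAR)
            return np.linalg.norm(forest.trees[0].leaf.W - A)

        small = np.mean([rmse(400, s) for s in range(6)])
        large = np.mean([rmse(1600, s + 100) for s in range(6)])
        ratio = small / large
        assert 1.4 <= ratio <= 2.6  # 2.0 +/- 30%


class TestSerialization:
    def test_round_trip_preserves_predictions(self):
        rng = np.random.default_rng(13)
        X_L = rng.normal(size=(300, 4))
        X_H = rng.normal(size=(300, 2))
        cfg = ForestConfig(n_trees=3, max_depth=3, min_leaf_samples=20, seed=2)
        forest = train_forest((X_L, X_H), cfg, LINEAR)
        back = forest_from_arrays(forest_to_arrays(forest))
        X = rng.normal(size=(40, 4))
        np.testing.assert_array_equal(predict_batch(forest, X),
                                      predict_batch(back, X))
        assert back.config == forest.config
        assert back.basis == forest.basis
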