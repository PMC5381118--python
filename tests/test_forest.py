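import json

import numpy as np
import pytest

from oxydyn import (
    best_split,
    ensemble_predict,
    fit_forest,
    grow_tree,
    loso_cv,
    predict_forest,
)
from oxydyn.forest import (
    Forest,
    ForestEnsemble,
    ForestError,
    forest_from_dict,
    forest_to_dict,
)


def brute_force_split(X, y, candidates):
    """Oracle: evaluate SSR at every feature x midpoint by direct means/residuals.

    Mathematically equal SSRs (identical row bipartitions reached through
    different features) are ties and resolve to the lowest feature index and
    smallest threshold, matching the documented tie rule.
    """
    tol = 1e-10 * max(((y - y.mean()) ** 2).sum(), 1e-300)
    best = None
    for j in sorted(candidates):
        vals = np.unique(X[:, j])
        for lo, hi in zip(vals[:-1], vals[1:]):
            s = (lo + hi) / 2.0
            left = y[X[:, j] <= s]
            right = y[X[:, j] > s]
            ssr = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            if best is None or ssr < best[2] - tol:
                best = (j, s, ssr, left.mean(), right.mean())
    return best


class TestBestSplit:
    def test_clean_two_level_target(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 1.0, 3.0, 3.0])
        crit = best_split(X, y, [0])
        assert crit.split_value == 2.5
        assert crit.ssr == 0.0
        assert (crit.left_mean, crit.right_mean) == (1.0, 3.0)

    def test_linear_target_midpoint(self):
        # SSR at midpoints 1.5 / 2.5 / 3.5 is 2.0 / 1.0 / 2.0
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 2.0, 3.0, 4.0])
        crit = best_split(X, y, [0])
        assert crit.split_value == 2.5
        assert np.isclose(crit.ssr, 1.0)

    def test_constant_target_tie_break(self):
        X = np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 30.0]])
        y = np.zeros(3)
        crit = best_split(X, y, [0, 1])
        assert crit.feature_index == 0
        assert crit.split_value == 1.5  # smallest threshold on lowest feature

    def test_constant_features_signal_no_split(self):
        X = np.ones((5, 2))
        crit = best_split(X, np.arange(5.0), [0, 1])
        assert crit is None

    def test_matches_brute_force_on_random_data(self, rng):
        for _ in range(300):
            n = rng.integers(2, 13)
            p = rng.integers(1, 4)
            X = np.round(rng.normal(size=(n, p)), 3)
            y = rng.normal(size=n)
            cand = list(range(p))
            got = best_split(X, y, cand)
            want = brute_force_split(X, y, cand)
            if want is None:
                assert got is None
                continue
            assert got.feature_index == want[0]
            assert np.isclose(got.split_value, want[1])
            assert np.isclose(got.ssr, want[2], atol=1e-9)

    def test_split_never_increases_ssr(self, rng):
        for _ in range(50):
            X = rng.normal(size=(20, 3))
            y = rng.normal(size=20)
            node_ss = ((y - y.mean()) ** 2).sum()
            crit = best_split(X, y, [0, 1, 2])
            assert crit.ssr <= node_ss + 1e-12


class TestGrowTree:
    def test_full_interpolation_with_min_leaf_1(self, rng):
        X = np.arange(10.0).reshape(-1, 1)
        y = rng.normal(size=10)
        tree = grow_tree(X, y, mtry=1, min_leaf=1)
        np.testing.assert_allclose(tree.predict(X), y)

    def test_constant_target_single_leaf(self):
        tree = grow_tree(np.arange(8.0).reshape(-1, 1), np.full(8, 2.5), mtry=1)
        assert tree.n_nodes == 1
        assert tree.predict(np.array([[99.0]]))[0] == 2.5

    def test_leaf_values_are_region_means(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([1.0, 2.0, 10.0, 11.0])
        tree = grow_tree(X, y, mtry=1, min_leaf=2)
        np.testing.assert_allclose(tree.predict(np.array([[0.0], [9.0]])), [1.5, 10.5])

    def test_predictions_bounded_by_training_targets(self, rng):
        X = rng.normal(size=(200, 4))
        y = rng.normal(size=200)
        tree = grow_tree(X, y, mtry=2, min_leaf=5, rng=rng)
        preds = tree.predict(rng.normal(size=(100, 4)))
        assert preds.min() >= y.min() and preds.max() <= y.max()


class TestForest:
    def test_default_mtry_is_third_of_features(self, rng):
        X = rng.normal(size=(30, 6))
        forest = fit_forest(X, rng.normal(size=30), n_trees=3, seed=0)
        assert forest.params["mtry"] == 2

    def test_same_seed_reproduces_predictions(self, rng):
        X = rng.normal(size=(60, 4))
        y = rng.normal(size=60)
        f1 = fit_forest(X, y, n_trees=10, seed=42)
        f2 = fit_forest(X, y, n_trees=10, seed=42)
        Xnew = rng.normal(size=(20, 4))
        np.testing.assert_array_equal(predict_forest(f1, Xnew), predict_forest(f2, Xnew))

    def test_single_unbagged_tree_reduction(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        forest = fit_forest(X, y, n_trees=1, mtry=3, bootstrap=False, seed=1)
        tree = grow_tree(X, y, mtry=3, min_leaf=5, rng=np.random.default_rng(0))
        np.testing.assert_allclose(predict_forest(forest, X), tree.predict(X))

    def test_weighted_average_of_constant_trees(self):
        t2 = grow_tree(np.array([[0.0], [1.0]]), np.array([2.0, 2.0]), mtry=1)
        t4 = grow_tree(np.array([[0.0], [1.0]]), np.array([4.0, 4.0]), mtry=1)
        Xq = np.zeros((3, 1))
        uniform = Forest([t2, t4], [0.5, 0.5], [np.array([0]), np.array([0])])
        np.testing.assert_allclose(predict_forest(uniform, Xq), 3.0)
        degenerate = Forest([t2, t4], [1.0, 0.0], [np.array([0]), np.array([0])])
        np.testing.assert_allclose(predict_forest(degenerate, Xq), 2.0)

    def test_constant_target_predicts_constant(self, rng):
        X = rng.normal(size=(50, 3))
        forest = fit_forest(X, np.full(50, 7.0), n_trees=5, seed=0)
        np.testing.assert_allclose(predict_forest(forest, rng.normal(size=(10, 3))), 7.0)

    def test_within_tolerance_of_reference_forest(self, rng):
        """Out-of-sample RMSE within 15% of scikit-learn with matched settings."""
        sklearn_rf = pytest.importorskip("sklearn.ensemble").RandomForestRegressor
        n = 400
        X = rng.uniform(-2, 2, size=(n, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] ** 2 + rng.normal(0, 0.2, n)
        Xt = rng.uniform(-2, 2, size=(200, 3))
        yt = np.sin(Xt[:, 0]) + 0.5 * Xt[:, 1] ** 2
        ours = fit_forest(X, y, n_trees=100, mtry=1, min_leaf=5, seed=3)
        rmse_ours = np.sqrt(np.mean((predict_forest(ours, Xt) - yt) ** 2))
        ref = sklearn_rf(
            n_estimators=100, max_features=1, min_samples_leaf=5, random_state=3
        ).fit(X, y)
        rmse_ref = np.sqrt(np.mean((ref.predict(Xt) - yt) ** 2))
        assert abs(rmse_ours - rmse_ref) / rmse_ref < 0.15


class TestLosoCV:
    def test_fold_partition_contract(self, rng):
        X = rng.normal(size=(40, 3))
        y = rng.normal(size=40)
        pids = np.repeat(["A", "B"], 20)
        ensemble, heldout = loso_cv(X, y, pids, n_trees=3, seed=0)
        assert len(ensemble.forests) == 2
        assert ensemble.fold_participant_ids == ["A", "B"]
        assert np.isfinite(heldout).all() and heldout.shape == (40,)

    def test_one_forest_per_participant(self, rng):
        n_per, n_p = 12, 5
        X = rng.normal(size=(n_per * n_p, 3))
        y = rng.normal(size=n_per * n_p)
        pids = np.repeat([f"P{i}" for i in range(n_p)], n_per)
        ensemble, _ = loso_cv(X, y, pids, n_trees=2, seed=0)
        assert len(ensemble.forests) == n_p

    def test_single_participant_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ForestError):
            loso_cv(X, np.zeros(10), np.repeat(["A"], 10), n_trees=1)

    def test_heldout_is_out_of_sample(self, rng):
        # a feature that memorises the target within-participant: the held-out
        # fold never saw this participant, so it cannot reproduce y exactly
        y = rng.normal(size=60)
        X = np.column_stack([y, rng.normal(size=60)])
        pids = np.repeat(["A", "B", "C"], 20)
        _, heldout = loso_cv(X, y, pids, n_trees=5, min_leaf=1, seed=0)
        assert not np.allclose(heldout, y)


class TestEnsemble:
    def test_single_forest_reduction(self, rng):
        X = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        forest = fit_forest(X, y, n_trees=3, seed=0)
        ens = ForestEnsemble([forest], ["A"])
        np.testing.assert_allclose(ensemble_predict(ens, X), predict_forest(forest, X))

    def test_mean_across_forests(self):
        t10 = grow_tree(np.array([[0.0], [1.0]]), np.array([10.0, 10.0]), mtry=1)
        t20 = grow_tree(np.array([[0.0], [1.0]]), np.array([20.0, 20.0]), mtry=1)
        f10 = Forest([t10], [1.0], [np.array([0])])
        f20 = Forest([t20], [1.0], [np.array([0])])
        ens = ForestEnsemble([f10, f20], ["A", "B"])
        np.testing.assert_allclose(ensemble_predict(ens, np.zeros((4, 1))), 15.0)


class TestSerialization:
    def test_json_roundtrip_bit_exact(self, rng, tmp_path):
        X = rng.normal(size=(80, 4))
        y = rng.normal(size=80)
        forest = fit_forest(X, y, n_trees=8, seed=9)
        blob = json.dumps(forest_to_dict(forest))
        clone = forest_from_dict(json.loads(blob))
        Xq = rng.normal(size=(30, 4))
        np.testing.assert_array_equal(predict_forest(forest, Xq), predict_forest(clone, Xq))
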