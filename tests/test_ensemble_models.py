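import numpy as np
import pytest

from gsrank.ensemble_models import (
    Ensemble,
    GradientBoostedTrees,
    LambdaMART,
    TreeLearnerContract,
    delta_ndcg_swap,
    fit_regression_tree,
    lambda_gradient,
    predict_ensemble,
)
from gsrank.metrics import induced_permutation, ndcg_at_k


class TestRegressionTree:
    def test_constant_targets_single_leaf(self, rng):
        X = rng.integers(0, 3, size=(10, 4)).astype(float)
        tree = fit_regression_tree(X, np.full(10, 2.5),
                                   TreeLearnerContract(seed=0))
        np.testing.assert_allclose(tree.predict(X), 2.5)

    def test_depth1_perfect_split_gives_group_means(self):
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([1.0, 3.0, 10.0, 14.0])
        tree = fit_regression_tree(
            X, y, TreeLearnerContract(max_depth=1,
                                      max_features_fraction=1.0, seed=0)
        )
        np.testing.assert_allclose(tree.predict(X), [2, 2, 12, 12])

    def test_same_seed_same_tree(self, rng):
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        c = TreeLearnerContract(max_depth=3, max_features_fraction=0.5, seed=7)
        p1 = fit_regression_tree(X, y, c).predict(X)
        p2 = fit_regression_tree(X, y, c).predict(X)
        np.testing.assert_array_equal(p1, p2)


class TestGBRT:
    def test_zero_stages_predicts_mean(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.normal(size=10)
        model = GradientBoostedTrees(n_estimators=0).fit(X, y)
        np.testing.assert_allclose(model.predict(X), y.mean())

    def test_training_mse_non_increasing(self, small_sim):
        X = small_sim.dataset.markers.values.astype(float)
        y = small_sim.dataset.traits[0].values
        model = GradientBoostedTrees(n_estimators=40, learning_rate=0.1,
                                     random_state=0).fit(X, y)
        assert np.all(np.diff(model.train_mse_path_) <= 1e-10)

    def test_more_stages_fit_better(self, small_sim):
        X = small_sim.dataset.markers.values.astype(float)
        y = small_sim.dataset.traits[0].values
        few = GradientBoostedTrees(n_estimators=5, learning_rate=0.1,
                                   random_state=0).fit(X, y)
        many = GradientBoostedTrees(n_estimators=50, learning_rate=0.1,
                                    random_state=0).fit(X, y)
        assert many.train_mse_path_[-1] < few.train_mse_path_[-1]

    def test_interpolation_limit(self, rng):
        """lr=1, unlimited depth, all features: boosting drives train MSE
        to ~0 on tie-free data."""
        X = rng.normal(size=(25, 8))
        y = rng.normal(size=25)
        model = GradientBoostedTrees(
            n_estimators=10, learning_rate=1.0, max_depth=None,
            max_features=1.0, random_state=0,
        ).fit(X, y)
        assert model.train_mse_path_[-1] == pytest.approx(0.0, abs=1e-20)

    def test_same_seed_identical_model(self, small_sim):
        X = small_sim.dataset.markers.values.astype(float)
        y = small_sim.dataset.traits[0].values
        a = GradientBoostedTrees(n_estimators=10, random_state=3).fit(X, y)
        b = GradientBoostedTrees(n_estimators=10, random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestPredictEnsemble:
    def test_empty_stages_is_base_value(self, rng):
        X = rng.normal(size=(5, 2))
        ens = Ensemble(base_value=1.5)
        np.testing.assert_allclose(ens.predict(X), 1.5)

    def test_matches_naive_accumulation(self, small_sim):
        X = small_sim.dataset.markers.values.astype(float)
        y = small_sim.dataset.traits[0].values
        model = GradientBoostedTrees(n_estimators=15, random_state=0).fit(X, y)
        ens = model.ensemble_
        naive = np.full(X.shape[0], ens.base_value)
        for tree, w in zip(ens.trees, ens.weights):
            naive = naive + w * tree.predict(X)
        np.testing.assert_allclose(predict_ensemble(model, X), naive)

    def test_marker_count_mismatch(self, small_sim, rng):
        X = small_sim.dataset.markers.values.astype(float)
        y = small_sim.dataset.traits[0].values
        model = GradientBoostedTrees(n_estimators=2, random_state=0).fit(X, y)
        with pytest.raises(ValueError, match="mismatch"):
            predict_ensemble(model, rng.normal(size=(3, X.shape[1] + 1)))


class TestDeltaNDCGSwap:
    def test_both_below_k_is_zero(self, rng):
        y = rng.uniform(0, 5, size=8)
        perm = induced_permutation(rng.normal(size=8))
        i, j = perm[5], perm[7]  # ranks 6 and 8, both beyond k=3
        assert delta_ndcg_swap(y, perm, i, j, k=3) == 0.0

    def test_equal_gains_is_zero(self):
        y = np.array([2.0, 2.0, 1.0])
        perm = np.array([0, 1, 2])
        assert delta_ndcg_swap(y, perm, 0, 1, k=2) == 0.0

    def test_matches_direct_recomputation(self, rng):
        """Swap formula equals NDCG recomputed on both full rankings."""
        for _ in range(20):
            y = rng.uniform(0, 5, size=4)
            s = rng.normal(size=4)
            perm = induced_permutation(s)
            i, j = perm[0], perm[2]  # ranks 1 and 3
            k = int(rng.integers(1, 5))
            swapped = perm.copy()
            swapped[[0, 2]] = swapped[[2, 0]]
            from gsrank.metrics import dcg_at_k

            ideal = dcg_at_k(y, induced_permutation(y), k)
            before = dcg_at_k(y, perm, k) / ideal
            after = dcg_at_k(y, swapped, k) / ideal
            assert delta_ndcg_swap(y, perm, i, j, k) == pytest.approx(
                abs(after - before), abs=1e-12
            )

    def test_symmetric_in_items(self, rng):
        y = rng.uniform(0, 5, size=6)
        perm = induced_permutation(rng.normal(size=6))
        assert delta_ndcg_swap(y, perm, 1, 4, 3) == pytest.approx(
            delta_ndcg_swap(y, perm, 4, 1, 3)
        )


class TestLambdaGradient:
    def test_constant_trait_errors(self, rng):
        with pytest.raises(ValueError, match="constant"):
            lambda_gradient(np.ones(5), rng.normal(size=5), 3)

    def test_sums_to_zero_by_antisymmetry(self, rng):
        for _ in range(5):
            y = rng.uniform(0, 5, size=12)
            s = rng.normal(size=12)
            lam = lambda_gradient(y, s, 5).lambda_vector
            assert lam.sum() == pytest.approx(0.0, abs=1e-12)

    def test_pairs_with_both_items_below_k_contribute_nothing(self, rng):
        """Dropping every preference pair whose items both rank below k
        leaves the lambda vector unchanged: such swaps cannot move
        NDCG@k."""
        from scipy.special import expit

        from gsrank.ensemble_models import delta_ndcg_swap
        from gsrank.metrics import pair_partition

        y = rng.uniform(0, 5, size=10)
        s = rng.normal(size=10)
        k = 3
        perm = induced_permutation(s)
        ranks = np.empty(10, dtype=int)
        ranks[perm] = np.arange(1, 11)
        rebuilt = np.zeros(10)
        for i, j in pair_partition(y, s).preference:
            if ranks[i] > k and ranks[j] > k:
                assert delta_ndcg_swap(y, perm, i, j, k) == 0.0
                continue  # omitted entirely
            push = delta_ndcg_swap(y, perm, i, j, k) * expit(-(s[i] - s[j]))
            rebuilt[i] += push
            rebuilt[j] -= push
        np.testing.assert_allclose(
            rebuilt, lambda_gradient(y, s, k).lambda_vector, atol=1e-12
        )

    def test_preferred_item_pushed_up(self):
        y = np.array([2.0, 1.0])
        s = np.array([0.0, 0.0])
        lam = lambda_gradient(y, s, 2).lambda_vector
        assert lam[0] > 0 > lam[1]


class TestLambdaMART:
    def test_zero_stages_constant_scores(self, rng):
        X = rng.normal(size=(10, 3))
        y = rng.uniform(0, 5, size=10)
        model = LambdaMART(k=5, n_estimators=0).fit(X, y)
        np.testing.assert_allclose(model.predict(X), 0.0)

    def test_negative_traits_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        with pytest.raises(ValueError, match="nonnegative"):
            LambdaMART().fit(X, np.array([-1.0, 0, 1, 2, 3, 4]))

    def test_learns_single_marker_signal(self, rng):
        """Noiseless trait driven by one marker: training NDCG@5 -> 1."""
        X = rng.integers(0, 3, size=(20, 1)).astype(float)
        y = 2.0 * X[:, 0]  # within-class ties: any within-class order is ideal
        model = LambdaMART(k=5, n_estimators=100, learning_rate=0.3,
                           max_features=1.0, random_state=0).fit(X, y)
        assert ndcg_at_k(y, model.predict(X), 5) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_same_seed_identical_ensemble(self, small_sim):
        X = small_sim.dataset.markers.values.astype(float)
        y = small_sim.dataset.traits[0].values
        a = LambdaMART(k=10, n_estimators=10, random_state=2).fit(X, y)
        b = LambdaMART(k=10, n_estimators=10, random_state=2).fit(X, y)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))


class TestRandomForestContract:
    def test_averaging_identical_trees_equals_single_tree(self, rng):
        """Duplicated deterministic trees average to the same prediction."""
        from sklearn.ensemble import RandomForestRegressor

        X = rng.normal(size=(30, 5))
        y = rng.normal(size=30)
        one = RandomForestRegressor(n_estimators=1, bootstrap=False,
                                    max_features=1.0, random_state=0).fit(X, y)
        many = RandomForestRegressor(n_estimators=10, bootstrap=False,
                                     max_features=1.0, random_state=0).fit(X, y)
        np.testing.assert_allclose(one.predict(X), many.predict(X))
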