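import numpy as np
import pytest

import oracles
from pcgkit.classify import (CLASSES, CostMatrix, cross_validate,
                             decide_with_cost, fit_knn, fit_subspace_ensemble,
                             holdout_split, knn_predict_proba, predict,
                             predict_proba, tune_hyperparameters)
from pcgkit.io import DatasetManifest
from pcgkit.metrics import confusion_from_labels, compute_metrics


def _gaussians(seed, n=100, shift=3.0, p=2):
    rng = np.random.default_rng(seed)
    y = np.array(["normal"] * (n // 2) + ["abnormal"] * (n - n // 2))
    X = rng.standard_normal((n, p))
    X[y == "abnormal", 0] += 2 * shift
    X[y == "normal", 0] -= 0.0
    return X, y


class TestKNN:
    def test_exact_training_point_k1(self):
        X, y = _gaussians(0, n=20)
        model = fit_knn(X, y, kind="fine_knn")
        post = knn_predict_proba(model, X[:3])
        for i in range(3):
            assert post[i, CLASSES.index(y[i])] == 1.0

    def test_vote_fraction_k3(self):
        X = np.array([[0.0], [0.1], [5.0]])
        y = np.array(["abnormal", "abnormal", "normal"])
        model = fit_knn(X, y, kind="fine_knn", k=3)
        post = knn_predict_proba(model, np.array([[0.05]]))
        assert post[0, CLASSES.index("abnormal")] == pytest.approx(2 / 3)

    def test_rows_sum_to_one(self):
        X, y = _gaussians(1)
        model = fit_knn(X, y, kind="weighted_knn")
        post = knn_predict_proba(model, X)
        assert np.allclose(post.sum(axis=1), 1.0)

    @pytest.mark.parametrize("metric", ["euclidean", "cityblock", "chebyshev",
                                        "cosine"])
    def test_neighbor_sets_match_exhaustive_search(self, metric, rng):
        train = rng.standard_normal((50, 2))
        y = np.array(["normal", "abnormal"] * 25)
        queries = rng.standard_normal((10, 2))
        from sklearn.neighbors import NearestNeighbors
        from pcgkit.classify import _METRIC_MAP
        nn = NearestNeighbors(n_neighbors=5, metric=_METRIC_MAP[metric],
                              algorithm="brute").fit(train)
        _, idx = nn.kneighbors(queries)
        for q, row in zip(queries, idx):
            expected = oracles.knn_neighbors(train, q, 5, metric)
            assert set(row) == set(expected)

    def test_dimension_mismatch_rejected(self):
        X, y = _gaussians(2)
        model = fit_knn(X, y)
        with pytest.raises(ValueError, match="features"):
            knn_predict_proba(model, np.zeros((1, 5)))


class TestCostDecision:
    def test_expected_cost_arithmetic(self):
        cost = CostMatrix(10, 1)
        post = np.array([[0.8, 0.2]])  # (normal, abnormal)
        assert decide_with_cost(post, cost) == ["abnormal"]  # 0.8 < 2.0
        post = np.array([[0.95, 0.05]])
        assert decide_with_cost(post, cost) == ["normal"]

    def test_threshold_is_one_eleventh(self):
        cost = CostMatrix(10, 1)
        assert cost.abnormal_threshold == pytest.approx(1 / 11)
        eps = 1e-9
        above = np.array([[1 - (1 / 11 + eps), 1 / 11 + eps]])
        below = np.array([[1 - (1 / 11 - eps), 1 / 11 - eps]])
        assert decide_with_cost(above, cost) == ["abnormal"]
        assert decide_with_cost(below, cost) == ["normal"]

    def test_symmetric_costs_are_argmax(self):
        cost = CostMatrix(1, 1)
        post = np.array([[0.6, 0.4], [0.3, 0.7]])
        assert decide_with_cost(post, cost) == ["normal", "abnormal"]

    def test_negative_posterior_rejected(self):
        with pytest.raises(ValueError):
            decide_with_cost(np.array([[-0.1, 1.1]]), CostMatrix())

    def test_cost_monotonicity_on_fixed_posteriors(self, rng):
        """Raising the miss cost never decreases sensitivity and never
        increases specificity."""
        post = rng.dirichlet([1, 1], size=300)
        y = np.where(rng.random(300) < 0.4, "abnormal", "normal")
        prev_sens, prev_spec = -1.0, 2.0
        for cfn in (1.0, 2.0, 5.0, 10.0, 50.0):
            labels = decide_with_cost(post, CostMatrix(cfn, 1.0))
            rep = compute_metrics(confusion_from_labels(y.tolist(), labels))
            assert rep.sensitivity >= prev_sens
            assert rep.specificity <= prev_spec
            prev_sens, prev_spec = rep.sensitivity, rep.specificity


class TestSubspaceEnsemble:
    def test_degenerate_ensemble_equals_base(self):
        X, y = _gaussians(2)
        ens = fit_subspace_ensemble(X, y, n_learners=1, subspace_dim=2,
                                    base="discriminant", seed=0)
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        lda = LinearDiscriminantAnalysis().fit(ens.state["train_X"], y)
        post = predict_proba(ens, X)
        ref = lda.predict_proba(ens.state["train_X"])
        cols = [list(lda.classes_).index(c) for c in CLASSES]
        assert np.allclose(post, ref[:, cols], atol=1e-9)

    def test_separable_data_high_accuracy(self):
        X, y = _gaussians(2, n=100, shift=3.0, p=2)
        ens = fit_subspace_ensemble(X, y, n_learners=10, subspace_dim=1, seed=2)
        labels = decide_with_cost(predict_proba(ens, X), CostMatrix(1, 1))
        assert np.mean(np.array(labels) == y) >= 0.99

    def test_same_seed_same_members(self):
        X, y = _gaussians(3, p=6)
        a = fit_subspace_ensemble(X, y, n_learners=5, subspace_dim=3, seed=9)
        b = fit_subspace_ensemble(X, y, n_learners=5, subspace_dim=3, seed=9)
        for ma, mb in zip(a.state["members"], b.state["members"]):
            assert np.array_equal(ma["cols"], mb["cols"])
        assert np.allclose(predict_proba(a, X), predict_proba(b, X))

    def test_knn_base_supported(self):
        X, y = _gaussians(4, p=4)
        ens = fit_subspace_ensemble(X, y, n_learners=5, subspace_dim=2,
                                    base="knn", seed=1)
        post = predict_proba(ens, X)
        assert np.allclose(post.sum(axis=1), 1.0)


class TestCrossValidate:
    def test_separable_high_pooled_accuracy(self):
        X, y = _gaussians(5, n=100)
        res = cross_validate(X, y, {"kind": "weighted_knn"}, seed=1,
                             cost=CostMatrix(1, 1))
        assert res.pooled.accuracy >= 0.98

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((200, 5))
        y = np.array(["normal", "abnormal"] * 100)
        res = cross_validate(X, y, {"kind": "fine_knn"}, seed=1,
                             cost=CostMatrix(1, 1))
        assert 0.35 <= res.pooled.accuracy <= 0.65

    def test_fold_sizes_balanced(self):
        X, y = _gaussians(6, n=103)
        res = cross_validate(X, y, seed=0)
        sizes = [cm.total for cm in res.fold_matrices]
        assert max(sizes) - min(sizes) <= 2
        assert sum(sizes) == 103

    def test_small_class_rejected(self):
        X = np.zeros((6, 2))
        y = np.array(["normal"] * 4 + ["abnormal"] * 2)
        with pytest.raises(ValueError, match="fewer"):
            cross_validate(X, y, n_folds=5)


class TestHoldoutSplit:
    def _manifest(self, n_normal=80, n_abnormal=20):
        entries = ([(f"n{i}", f"n{i}.wav", "normal") for i in range(n_normal)]
                   + [(f"a{i}", f"a{i}.wav", "abnormal") for i in range(n_abnormal)])
        return DatasetManifest(entries)

    def test_stratified_80_20(self):
        train, test = holdout_split(self._manifest(), 0.2, seed=1)
        assert len(train) == 80 and len(test) == 20
        assert abs(test.class_counts["abnormal"] - 4) <= 1

    def test_reproducible_and_disjoint(self):
        man = self._manifest()
        t1, s1 = holdout_split(man, 0.2, seed=3)
        t2, s2 = holdout_split(man, 0.2, seed=3)
        assert [e[0] for e in t1.entries] == [e[0] for e in t2.entries]
        assert not ({e[0] for e in t1.entries} & {e[0] for e in s1.entries})

    def test_different_seeds_differ(self):
        man = self._manifest()
        _, s1 = holdout_split(man, 0.2, seed=1)
        _, s2 = holdout_split(man, 0.2, seed=2)
        assert {e[0] for e in s1.entries} != {e[0] for e in s2.entries}

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(self._manifest(), 1.5)


class TestTuning:
    def test_single_point_grid(self):
        X, y = _gaussians(8, n=60)
        best, table = tune_hyperparameters(
            X, y, grid={"metric": ["euclidean"], "k": [3]}, seed=0)
        assert (best["metric"], best["k"]) == ("euclidean", 3)
        assert len(table) == 1

    def test_table_has_one_row_per_grid_point(self):
        X, y = _gaussians(9, n=60)
        _best, table = tune_hyperparameters(
            X, y, grid={"metric": ["euclidean", "cityblock"], "k": [1, 5, 9]},
            seed=0)
        assert len(table) == 6

    def test_noisy_boundary_prefers_k_above_one(self):
        picks = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 160
            y = np.array(["normal", "abnormal"] * (n // 2))
            X = rng.standard_normal((n, 2))
            X[y == "abnormal", 0] += 1.2  # heavily overlapping classes
            best, _ = tune_hyperparameters(
                X, y, grid={"metric": ["euclidean"], "k": [1, 5, 10, 15]},
                seed=seed, cost=CostMatrix(1, 1))
            picks.append(best["k"])
        assert sum(k > 1 for k in picks) >= 4


class TestNoLeakage:
    def test_test_fold_labels_do_not_touch_scaler(self):
        X, y = _gaussians(10, n=60)
        model = fit_knn(X[:40], y[:40])
        mean_before = model.scaler_mean.copy()
        y_corrupt = y.copy()
        y_corrupt[40:] = "abnormal"
        model2 = fit_knn(X[:40], y_corrupt[:40])
        assert np.array_equal(model2.scaler_mean, mean_before)
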