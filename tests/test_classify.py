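import numpy as np
import pytest

from ecgrqa import LatentCNNClassifier, RUSBoostClassifier, StackConfig, \
    StackedRQAClassifier, evaluate, fit_stacked, predict

from oracles import confusion_bf


def gaussian_clouds(n_per_class, n_features=10, classes=("A", "B", "C", "D", "E"),
                    sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X, y = [], []
    for i, cls in enumerate(classes):
        centre = rng.normal(0, 1, n_features) * 0 + np.eye(len(classes),
                                                           n_features)[i] * sep
        X.append(centre + rng.normal(0, 1.0, (n_per_class, n_features)))
        y += [cls] * n_per_class
    return np.vstack(X), np.asarray(y)


class TestEvaluate:
    def test_perfect_prediction(self):
        labels = ["HC", "MI", "BBB", "CM", "DR"] * 2
        res = evaluate(labels, labels)
        assert res.accuracy == 1.0
        assert all(m["f1"] == 1.0 for m in res.per_class.values())

    def test_hand_counted_contingency(self):
        truth = ["HC", "HC", "MI", "MI"]
        pred = ["HC", "MI", "MI", "MI"]
        res = evaluate(pred, truth, class_order=("HC", "MI"))
        assert res.accuracy == 0.75
        assert res.per_class["MI"]["precision"] == pytest.approx(2 / 3)
        assert res.per_class["MI"]["recall"] == 1.0
        assert res.per_class["MI"]["f1"] == pytest.approx(0.8)

    def test_zero_division_flagged(self):
        res = evaluate(["HC", "MI"], ["HC", "HC"], class_order=("HC", "MI"))
        assert res.per_class["MI"]["precision"] == 0.0
        assert res.undefined_metrics

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            evaluate(["XX"], ["HC"])

    @pytest.mark.parametrize("seed", range(5))
    def test_confusion_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        order = ("HC", "MI", "BBB", "CM", "DR")
        truth = rng.choice(order, 40)
        pred = rng.choice(order, 40)
        res = evaluate(pred, truth)
        assert np.array_equal(res.confusion, confusion_bf(pred, truth, order))
        assert res.confusion.sum(axis=1).tolist() == [
            int((truth == c).sum()) for c in order]


class TestRUSBoost:
    def test_separable_data(self):
        X, y = gaussian_clouds(20, seed=1)
        clf = RUSBoostClassifier(n_estimators=30, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.9

    def test_proba_rows_sum_to_one(self):
        X, y = gaussian_clouds(10, seed=2)
        clf = RUSBoostClassifier(n_estimators=10, random_state=0).fit(X, y)
        assert np.allclose(clf.predict_proba(X).sum(axis=1), 1.0)

    def test_imbalanced_minority_recalled(self):
        rng = np.random.default_rng(3)
        X_maj = rng.normal(0, 1, (80, 4))
        X_min = rng.normal(3, 1, (12, 4))
        X = np.vstack([X_maj, X_min])
        y = np.array(["maj"] * 80 + ["min"] * 12)
        clf = RUSBoostClassifier(n_estimators=30, random_state=0).fit(X, y)
        pred = clf.predict(X_min)
        assert (pred == "min").mean() > 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            RUSBoostClassifier().fit(np.zeros((5, 2)), np.zeros(5))


class TestStacked:
    def test_separable_clouds_high_heldout_accuracy(self):
        X, y = gaussian_clouds(20, seed=4)
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(y))
        tr, te = idx[:70], idx[70:]
        clf = StackedRQAClassifier(seed=0).fit(X[tr], y[tr])
        assert (clf.predict(X[te]) == y[te]).mean() > 0.9

    def test_chance_level_on_permuted_labels(self):
        """Label-shuffled data scores near 1/k on held-out samples."""
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = rng.normal(0, 1, (100, 10))
            y = np.asarray((["A", "B", "C", "D", "E"] * 20))
            rng.shuffle(y)
            tr, te = np.arange(75), np.arange(75, 100)
            clf = StackedRQAClassifier(seed=seed).fit(X[tr], y[tr])
            accs.append((clf.predict(X[te]) == y[te]).mean())
        mean = np.mean(accs)
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(mean - 0.2) < max(3 * se, 0.1)

    def test_probabilities_normalised(self):
        X, y = gaussian_clouds(10, seed=5)
        clf = StackedRQAClassifier(seed=0).fit(X, y)
        labels, probs = predict(clf, X[:7])
        assert len(labels) == 7
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_training_set_consistency(self):
        X, y = gaussian_clouds(10, seed=6)
        clf = StackedRQAClassifier(seed=0).fit(X, y)
        assert np.array_equal(clf.predict(X), clf.predict(X))

    def test_empty_input(self):
        X, y = gaussian_clouds(10, seed=7)
        clf = StackedRQAClassifier(seed=0).fit(X, y)
        assert len(clf.predict(np.empty((0, X.shape[1])))) == 0

    def test_single_base_learner_rejected(self):
        from sklearn.svm import SVC
        clf = StackedRQAClassifier(base_estimators=[("svm", SVC())])
        with pytest.raises(ValueError, match="base learners"):
            clf.fit(*gaussian_clouds(10, seed=8))

    def test_small_class_stratification_error(self):
        X, y = gaussian_clouds(3, seed=9)  # 3 < cv_folds=5
        with pytest.raises(ValueError, match="fold"):
            StackedRQAClassifier(seed=0).fit(X, y)

    def test_insample_mode_fits(self):
        X, y = gaussian_clouds(4, seed=10, classes=("A", "B"))
        clf = StackedRQAClassifier(meta_features="insample", seed=0)
        clf.fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.8

    def test_stack_config_validation(self):
        with pytest.raises(ValueError):
            StackConfig(cv_folds=1)
        with pytest.raises(ValueError):
            StackConfig(meta_features="bogus")

    def test_not_worse_than_best_base(self):
        """Regression guard: stacking stays within 0.05 of the best base."""
        X, y = gaussian_clouds(16, sep=2.0, seed=11)
        rng = np.random.default_rng(1)
        idx = rng.permutation(len(y))
        tr, te = idx[:56], idx[56:]
        stacked = fit_stacked(X[tr], y[tr], StackConfig(seed=0))
        acc_stack = (stacked.predict(X[te]) == y[te]).mean()
        best_base = max(
            (est.predict(X[te]) == np.searchsorted(stacked.classes_, y[te]))
            .mean() for _, est in stacked.base_models_)
        assert acc_stack >= best_base - 0.05


class TestLatentCNN:
    def _latents(self, n_per_class=8, side=8, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for i, cls in enumerate(("HC", "MI", "BBB", "CM", "DR")):
            base = np.zeros((side, side))
            base[i % side] = 2.0  # one bright row per class
            X.append(base + rng.normal(0, 0.3, (n_per_class, side, side)))
            y += [cls] * n_per_class
        return np.vstack([x for x in X]).reshape(-1, side, side), np.asarray(y)

    def test_separable_latents_high_training_accuracy(self):
        X, y = self._latents()
        clf = LatentCNNClassifier(epochs=60, seed=0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.95

    def test_seeded_determinism(self):
        X, y = self._latents(4)
        p = [LatentCNNClassifier(epochs=10, seed=3).fit(X, y).predict(X)
             for _ in range(2)]
        assert np.array_equal(p[0], p[1])

    def test_single_class_rejected(self):
        X, _ = self._latents(4)
        with pytest.raises(ValueError):
            LatentCNNClassifier(epochs=1).fit(X, ["HC"] * len(X))

    def test_probabilities_normalised(self):
        X, y = self._latents(4)
        clf = LatentCNNClassifier(epochs=5, seed=0).fit(X, y)
        assert np.allclose(clf.predict_proba(X).sum(axis=1), 1.0, atol=1e-9)
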