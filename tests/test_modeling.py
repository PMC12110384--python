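"""Scenario pipelines, metrics, repeated CV, ROC/AUC and importances."""

import numpy as np
import pytest
from sklearn.pipeline import Pipeline

from hsilesion.modeling import (
    SCENARIO_HYPERPARAMETERS,
    build_pipeline,
    compute_metrics,
    feature_importance,
    is_probabilistic,
    repeated_cv_evaluate,
    roc_auc_ovr,
    split_train_test,
    zero_count_transform,
)


def _separable_data(rng, n_per_class=24, n_features=5):
    y = np.repeat(["I", "II", "III"], n_per_class)
    X = rng.standard_normal((y.size, n_features))
    X[:, 0] += 8.0 * (y == "I")
    X[:, 1] += 8.0 * (y == "II")
    return X, y


class TestZeroCount:
    def test_hand_counted_row(self):
        out = zero_count_transform(np.array([[0.0, 1.0, 0.0, 2.0]]))
        assert out[0, -2:].tolist() == [2.0, 2.0]

    def test_all_zero_row(self):
        out = zero_count_transform(np.zeros((1, 5)))
        assert out[0, -2:].tolist() == [5.0, 0.0]

    def test_matches_naive_loop(self, rng):
        X = rng.integers(-1, 2, size=(20, 6)).astype(float)
        out = zero_count_transform(X)
        for i in range(20):
            zeros = sum(1 for v in X[i] if v == 0)
            assert out[i, -2] == zeros and out[i, -1] == 6 - zeros
        np.testing.assert_array_equal(out[:, :6], X)


class TestPipelines:
    def test_scenario_i_hyperparameters(self):
        clf = build_pipeline("I", seed=0)
        assert clf.max_depth == 8
        assert clf.max_features == 0.2
        assert clf.min_samples_leaf == 4
        assert clf.min_samples_split == 5

    def test_scenario_ii_fixed_random_state_111(self):
        clf = build_pipeline("II", seed=12345)
        assert clf.random_state == 111
        assert clf.bootstrap is True
        assert clf.max_features == 0.25

    def test_scenario_iii_stage_order_and_no_probabilities(self):
        with pytest.warns(UserWarning, match="verbatim"):
            pipe = build_pipeline("III", seed=0)
        assert isinstance(pipe, Pipeline)
        assert [name for name, _ in pipe.steps] == \
            ["stacking", "zero_count", "linear_svc"]
        assert not is_probabilistic(pipe)
        assert is_probabilistic(build_pipeline("II"))

    def test_scenario_iii_trains_and_predicts(self, rng):
        X, y = _separable_data(rng)
        with pytest.warns(UserWarning):
            pipe = build_pipeline("III", seed=0)
        pipe.fit(X, y)
        assert set(pipe.predict(X)) <= set(y)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            build_pipeline("IV")

    def test_hyperparameter_record_matches_construction(self):
        assert SCENARIO_HYPERPARAMETERS["II"]["random_state"] == 111
        assert SCENARIO_HYPERPARAMETERS["III"]["sgd"]["power_t"] == 100.0


class TestSplit:
    def test_72_samples_split_54_18_balanced(self, rng):
        X, y = _separable_data(rng, n_per_class=24)
        lesions = np.tile([f"L{i}" for i in range(24)], 3)
        train, test = split_train_test(X, y, seed=0, lesion_ids=lesions)
        assert train.size == 54 and test.size == 18
        _, counts = np.unique(y[test], return_counts=True)
        assert counts.tolist() == [6, 6, 6]

    def test_no_lesion_spans_both_sides(self, rng):
        X, y = _separable_data(rng, n_per_class=24)
        lesions = np.tile([f"L{i}" for i in range(24)], 3)
        train, test = split_train_test(X, y, seed=3, lesion_ids=lesions)
        assert not set(lesions[train]) & set(lesions[test])

    def test_same_seed_same_split(self, rng):
        X, y = _separable_data(rng)
        a = split_train_test(X, y, seed=5, group_by_lesion=False)
        b = split_train_test(X, y, seed=5, group_by_lesion=False)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestMetrics:
    def test_perfect_prediction_scores_one(self):
        y = ["I", "II", "III"] * 4
        m = compute_metrics(y, y)
        for key in ("accuracy", "precision", "recall", "f1",
                    "balanced_accuracy"):
            assert m[key] == 1.0

    def test_constant_prediction_on_balanced_data_scores_chance(self):
        y_true = ["I"] * 4 + ["II"] * 4 + ["III"] * 4
        m = compute_metrics(y_true, ["I"] * 12)
        assert m["accuracy"] == pytest.approx(1 / 3)
        assert m["balanced_accuracy"] == pytest.approx(1 / 3)

    def test_hand_computed_confusion_matrix(self):
        m = compute_metrics([1, 1, 2, 3], [1, 2, 2, 3])
        assert m["accuracy"] == pytest.approx(0.75)
        assert m["recall"] == pytest.approx((0.5 + 1 + 1) / 3)

    def test_balanced_accuracy_equals_macro_recall(self, rng):
        for _ in range(10):
            y_true = rng.integers(0, 3, size=30)
            y_pred = rng.integers(0, 3, size=30)
            if np.unique(y_true).size < 3:
                continue
            m = compute_metrics(y_true, y_pred)
            assert m["balanced_accuracy"] == m["recall"]

    def test_absent_class_flagged_and_excluded(self):
        with pytest.warns(UserWarning, match="absent"):
            m = compute_metrics([1, 1, 2], [1, 3, 2])
        assert m["per_class"]["3"]["recall"] is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            compute_metrics([1, 2], [1])


class TestRepeatedCV:
    def test_separable_data_perfect_and_stable(self, rng):
        # plenty of samples per leaf so the conservative ensemble settings
        # (min_samples_leaf=5) cannot blur the planted separation
        X, y = _separable_data(rng, n_per_class=32)
        report = repeated_cv_evaluate(build_pipeline("II"), X, y,
                                      n_splits=4, n_repeats=5, seed=0)
        assert report.mean["accuracy"] == 1.0
        assert report.sd["accuracy"] == 0.0
        assert len(report.traces["accuracy"]) == 5

    def test_shuffled_labels_score_chance(self, rng):
        X, y = _separable_data(rng, n_per_class=16)
        y_shuffled = rng.permutation(y)
        report = repeated_cv_evaluate(build_pipeline("II"), X, y_shuffled,
                                      n_splits=4, n_repeats=10, seed=0)
        assert report.mean["accuracy"] == pytest.approx(1 / 3, abs=0.08)

    def test_class_too_small_raises_with_minimum(self, rng):
        X, y = _separable_data(rng, n_per_class=4)
        with pytest.raises(ValueError, match="needs >= 8"):
            repeated_cv_evaluate(build_pipeline("II"), X, y, n_splits=8,
                                 n_repeats=2)

    def test_reproducible_under_seed(self, rng):
        X, y = _separable_data(rng, n_per_class=16)
        a = repeated_cv_evaluate(build_pipeline("I", seed=1), X, y,
                                 n_splits=4, n_repeats=3, seed=9)
        b = repeated_cv_evaluate(build_pipeline("I", seed=1), X, y,
                                 n_splits=4, n_repeats=3, seed=9)
        assert a.traces == b.traces


def _auc_pairwise(scores, truth):
    """Mann-Whitney oracle: fraction of positive>negative pairs."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestROC:
    def test_auc_equals_pairwise_comparison_oracle(self):
        from sklearn.metrics import auc as sk_auc
        from sklearn.metrics import roc_curve

        scores = [0.1, 0.4, 0.35, 0.8, 0.65, 0.2, 0.9, 0.5]
        truth = [0, 0, 1, 1, 0, 0, 1, 1]
        fpr, tpr, _ = roc_curve(truth, scores)
        assert sk_auc(fpr, tpr) == pytest.approx(_auc_pairwise(scores, truth))

    def test_perfectly_separated_classes_reach_auc_one(self, rng):
        X, y = _separable_data(rng, n_per_class=16)
        result = roc_auc_ovr(build_pipeline("II"), X, y, k=4, seed=0)
        assert result["auc_mean"]["I"] == pytest.approx(1.0)
        assert result["auc_mean"]["II"] == pytest.approx(1.0)

    def test_random_scores_hover_at_half(self, rng):
        y = np.repeat(["I", "II", "III"], 134)  # ~400 samples
        X = rng.standard_normal((y.size, 4))
        result = roc_auc_ovr(build_pipeline("II"), X, y, k=4, seed=0)
        for cls in ("I", "II", "III"):
            assert result["auc_mean"][cls] == pytest.approx(0.5, abs=0.08)

    def test_nonprobabilistic_scenario_iii_rejected(self, rng):
        X, y = _separable_data(rng)
        with pytest.warns(UserWarning):
            pipe = build_pipeline("III")
        with pytest.raises(ValueError, match="non-probabilistic"):
            roc_auc_ovr(pipe, X, y)


class TestImportances:
    def test_sum_to_one(self, rng):
        X, y = _separable_data(rng)
        imp = feature_importance(X, y, seed=0)
        assert sum(imp.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(v >= 0 for v in imp.values())

    def test_planted_signal_gets_maximum_importance(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = rng.standard_normal((60, 6))
            X[:, 2] += 3.0 * y
            imp = feature_importance(X, y, seed=seed)
            assert max(imp, key=imp.get) == "f2"

    def test_permuting_columns_permutes_importances(self, rng):
        # symmetry holds in expectation; random thresholds/subsampling
        # consume the RNG in column order, so allow ensemble noise
        X, y = _separable_data(rng)
        names = ["a", "b", "c", "d", "e"]
        imp = feature_importance(X, y, feature_names=names, seed=0)
        perm = [2, 0, 1, 4, 3]
        imp_perm = feature_importance(X[:, perm], y,
                                      feature_names=[names[j] for j in perm],
                                      seed=0)
        for name in names:
            assert imp[name] == pytest.approx(imp_perm[name], abs=0.05)
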