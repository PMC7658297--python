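"""Metric suite, ROC/AUC, forest training, cross-validation, group means."""

import numpy as np
import pytest

from antioxseq.classify import (
    ConfusionCounts,
    auc_score,
    cross_validate,
    evaluate,
    group_feature_means,
    metrics_from_confusion,
    train_forest,
)

from conftest import make_matrix


def separable_matrix(rng, n_pos=30, n_neg=30, offset=3.0):
    labels = np.array([1] * n_pos + [0] * n_neg)
    values = rng.random((n_pos + n_neg, 2)) + offset * labels[:, None]
    return make_matrix(values, labels)


class TestMetrics:
    def test_benchmark_test_split_confusion(self):
        """Counts consistent with a 53+/52- independent test set."""
        rep = metrics_from_confusion(ConfusionCounts(TP=42, FN=11, TN=42, FP=10))
        assert rep.Sn == pytest.approx(0.792, abs=5e-4)
        assert rep.Sp == pytest.approx(0.808, abs=5e-4)
        assert rep.Acc == pytest.approx(0.800, abs=5e-4)
        assert rep.F == pytest.approx(0.800, abs=5e-4)
        assert rep.MCC == pytest.approx(0.600, abs=5e-4)

    def test_perfect_classifier(self):
        rep = metrics_from_confusion(ConfusionCounts(TP=50, FN=0, TN=50, FP=0))
        assert (rep.Sn, rep.Sp, rep.Acc, rep.F, rep.MCC) == (1, 1, 1, 1, 1)

    def test_degenerate_all_negative_predictions(self):
        rep = metrics_from_confusion(ConfusionCounts(TP=0, FN=10, TN=10, FP=0))
        assert rep.Sn == 0.0
        assert rep.F == 0.0
        assert rep.MCC == 0.0  # zero denominator convention

    def test_accuracy_recomputable_from_counts(self):
        cc = ConfusionCounts(TP=7, FN=3, TN=11, FP=4)
        rep = metrics_from_confusion(cc)
        assert rep.Acc == pytest.approx((cc.TP + cc.TN) / cc.total)

    def test_mcc_symmetry_under_class_swap(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(0, 30, 4)
            a = metrics_from_confusion(ConfusionCounts(int(tp), int(fp), int(fn), int(tn)))
            # swapping labels and predictions together: TP<->TN, FP<->FN
            b = metrics_from_confusion(ConfusionCounts(int(tn), int(fn), int(fp), int(tp)))
            assert abs(a.MCC) == pytest.approx(abs(b.MCC), abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 0)


class TestAUC:
    def test_scores_equal_labels(self):
        assert auc_score([1, 1, 0, 0], [1, 1, 0, 0]) == 1.0

    def test_all_scores_tied_is_chance(self):
        assert auc_score([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_pair_counting_oracle_small_case(self):
        labels = np.array([1, 1, 0, 0])
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        # exhaustive concordant-pair count: (0.9>0.6), (0.9>0.1), (0.4<0.6), (0.4>0.1)
        assert auc_score(labels, scores) == pytest.approx(3 / 4)

    def test_equals_normalized_mann_whitney_u(self, rng):
        """Trapezoidal ROC area == U/(n_pos*n_neg) with ties at half weight."""
        for _ in range(100):
            n = int(rng.integers(6, 40))
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            scores = rng.choice([0.1, 0.25, 0.5, 0.8, 0.9], size=n)  # force ties
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            u = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
            expect = u / (len(pos) * len(neg))
            assert auc_score(labels, scores) == pytest.approx(expect, abs=1e-10)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc_score([1, 1], [0.2, 0.3])


class TestForest:
    def test_separable_training_accuracy(self, rng):
        fm = separable_matrix(rng)
        bundle = train_forest(fm, trees=30, seed=0)
        assert (bundle.predict(fm) == fm.labels).all()

    def test_seed_determinism(self, rng):
        fm = separable_matrix(rng, offset=0.5)
        probe = separable_matrix(np.random.default_rng(99), offset=0.5)
        a = train_forest(fm, trees=30, seed=5).vote_fractions(probe)
        b = train_forest(fm, trees=30, seed=5).vote_fractions(probe)
        np.testing.assert_array_equal(a, b)

    def test_unknown_subset_feature_rejected(self, rng):
        fm = separable_matrix(rng)
        with pytest.raises(KeyError, match="nope"):
            train_forest(fm, subset=["f0", "nope"])

    def test_prediction_refuses_mismatched_columns(self, rng):
        fm = separable_matrix(rng)
        bundle = train_forest(fm, trees=10)
        other = make_matrix(rng.random((4, 2)), prefix="g", labels=np.array([1, 0, 1, 0]))
        with pytest.raises(ValueError, match="lacks"):
            evaluate(bundle, other)

    def test_evaluate_reports_full_suite(self, rng):
        fm = separable_matrix(rng)
        test = separable_matrix(np.random.default_rng(7))
        cc, rep = evaluate(train_forest(fm, trees=30), test)
        assert cc.total == test.n_samples
        assert rep.AUC == pytest.approx(1.0)
        assert rep.roc_points[0].tolist() == [0.0, 0.0]
        assert rep.roc_points[-1].tolist() == [1.0, 1.0]

    def test_evaluate_requires_labels(self, rng):
        fm = separable_matrix(rng)
        bundle = train_forest(fm, trees=10)
        unlabeled = make_matrix(rng.random((3, 2)))
        with pytest.raises(ValueError, match="label"):
            evaluate(bundle, unlabeled)


class TestCrossValidate:
    def test_fold_sizes_and_stratification(self, rng):
        labels = np.array([1] * 50 + [0] * 50)
        fm = make_matrix(rng.random((100, 3)), labels)
        res = cross_validate(fm, folds=10, trees=10, seed=0)
        assert len(res.fold_reports) == 10
        assert res.pooled_confusion.total == 100
        # each fold held out 10 samples at the global 1:1 ratio (+/- 1)
        for rep in res.fold_reports:
            assert rep.Acc >= 0.0  # smoke: reports populated

    def test_stratified_fold_class_ratio_within_one(self, rng):
        from sklearn.model_selection import StratifiedKFold

        labels = np.array([1] * 30 + [0] * 70)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
        for _, test_idx in cv.split(np.zeros((100, 1)), labels):
            n_pos = labels[test_idx].sum()
            assert abs(n_pos - 6) <= 1

    def test_class_smaller_than_folds_rejected(self, rng):
        labels = np.array([1] * 3 + [0] * 50)
        fm = make_matrix(rng.random((53, 2)), labels)
        with pytest.raises(ValueError, match="smaller"):
            cross_validate(fm, folds=10)

    def test_strong_signal_high_accuracy(self, rng):
        fm = separable_matrix(rng, n_pos=40, n_neg=40, offset=2.0)
        res = cross_validate(fm, folds=4, trees=30, seed=1)
        assert res.mean_report.Acc > 0.9


class TestGroupFeatureMeans:
    def test_hand_arithmetic(self):
        fm = make_matrix(np.array([[0.4], [0.1]]), np.array([1, 0]))
        df = group_feature_means(fm)
        assert df.loc["f0", "difference"] == pytest.approx(0.3)

    def test_constant_feature_zero_difference(self, rng):
        labels = np.array([1, 1, 0, 0])
        fm = make_matrix(np.ones((4, 2)), labels)
        assert (group_feature_means(fm)["difference"] == 0).all()

    def test_empty_class_rejected(self, rng):
        fm = make_matrix(rng.random((4, 2)), np.ones(4, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            group_feature_means(fm)
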