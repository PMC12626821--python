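"""Confusion matrix, the seven metrics, Dice, ROC/AUC, t-test, aggregation."""

import math

import numpy as np
import pytest
from scipy import stats

from hhbsnet.metrics import (MetricsReport, ZeroVarianceError, aggregate_runs,
                             confusion_matrix, dice_per_image, paired_t_test,
                             roc_auc_ovr, segmentation_metrics)

from _oracles import metrics_from_masks, pairwise_auc, tally_confusion


class TestConfusionMatrix:
    def test_perfect_prediction_is_diagonal(self, rng):
        ref = rng.integers(0, 4, size=(8, 8))
        cm = confusion_matrix(ref, ref, 4)
        assert np.all(cm == np.diag(np.diag(cm)))
        np.testing.assert_array_equal(np.diag(cm),
                                      np.bincount(ref.reshape(-1), minlength=4))

    def test_two_by_two_toy_example(self):
        ref = np.array([[0, 0], [1, 1]])
        pred = np.array([[0, 1], [1, 1]])
        np.testing.assert_array_equal(confusion_matrix(pred, ref, 2),
                                      [[1, 1], [0, 2]])

    def test_total_count_conserved(self, rng):
        for _ in range(10):
            ref = rng.integers(0, 2, size=(2, 2))
            pred = rng.integers(0, 2, size=(2, 2))
            assert confusion_matrix(pred, ref, 2).sum() == 4

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            confusion_matrix(np.zeros((2, 2), int), np.zeros((3, 3), int), 2)

    def test_labels_out_of_range_raise(self):
        with pytest.raises(ValueError, match="labels"):
            confusion_matrix(np.array([[5]]), np.array([[0]]), 2)


class TestSegmentationMetrics:
    def test_identity_confusion_gives_perfect_scores(self):
        report = segmentation_metrics(np.diag([10, 20, 30]))
        for name in ("miou", "acc", "f1", "mean_recall", "precision",
                     "dice", "specificity"):
            assert getattr(report, name) == 1.0

    def test_toy_matrix_hand_values(self):
        """[[1,1],[0,2]]: ACC 3/4, IoU (0.5, 2/3), MIoU 7/12."""
        report = segmentation_metrics(np.array([[1, 1], [0, 2]]))
        assert math.isclose(report.acc, 0.75)
        assert math.isclose(report.per_class["iou"][0], 0.5)
        assert math.isclose(report.per_class["iou"][1], 2 / 3)
        assert math.isclose(report.miou, (0.5 + 2 / 3) / 2, rel_tol=1e-12)

    def test_matches_brute_force_oracle_on_random_masks(self, rng):
        """50 random 16x16 6-class pairs, every metric to 1e-10."""
        for _ in range(50):
            ref = rng.integers(0, 6, size=(16, 16))
            pred = rng.integers(0, 6, size=(16, 16))
            cm = confusion_matrix(pred, ref, 6)
            np.testing.assert_array_equal(cm, tally_confusion(pred, ref, 6))
            report = segmentation_metrics(cm)
            expected = metrics_from_masks(pred, ref, 6)
            for name in ("miou", "acc", "f1", "mean_recall", "precision",
                         "dice", "specificity"):
                assert math.isclose(getattr(report, name), expected[name],
                                    abs_tol=1e-10), name

    def test_macro_f1_equals_macro_dice_from_global_counts(self, rng):
        ref = rng.integers(0, 4, size=(20, 20))
        pred = rng.integers(0, 4, size=(20, 20))
        report = segmentation_metrics(confusion_matrix(pred, ref, 4))
        for c in report.per_class["f1"]:
            assert math.isclose(report.per_class["f1"][c],
                                report.per_class["dice"][c], rel_tol=1e-12)

    def test_absent_class_skipped_in_macro_mean(self):
        """A class missing from both reference and prediction has no IoU."""
        cm = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 0]])
        report = segmentation_metrics(cm)
        assert 2 not in report.per_class["iou"]
        assert report.miou == 1.0

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            segmentation_metrics(np.zeros((3, 3)))

    def test_all_outputs_within_unit_interval(self, rng):
        cm = rng.integers(0, 50, size=(6, 6))
        cm[0, 0] += 1
        report = segmentation_metrics(cm)
        for name in ("miou", "acc", "f1", "mean_recall", "precision",
                     "dice", "specificity"):
            assert 0.0 <= getattr(report, name) <= 1.0

    def test_text_and_csv_serialization(self, tmp_path, rng):
        cm = np.diag([3, 4]) + 1
        report = segmentation_metrics(cm)
        text = report.to_text()
        assert text.startswith("miou ")
        path = tmp_path / "metrics.csv"
        report.write_csv(path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("metric,macro,class_0")
        assert len(lines) == 8


class TestDice:
    def test_identical_masks_score_one(self):
        m = np.array([[2, 2], [0, 0]])
        assert dice_per_image(m, m, 2) == 1.0

    def test_disjoint_sets_score_zero(self):
        a = np.array([[2, 0], [0, 0]])
        b = np.array([[0, 2], [0, 0]])
        assert dice_per_image(a, b, 2) == 0.0

    def test_partial_overlap_arithmetic(self):
        """|P| = 2, |R| = 4, overlap 2 -> 2/3."""
        pred = np.zeros((3, 3), int)
        pred[0, :2] = 2
        ref = np.zeros((3, 3), int)
        ref[0, :2] = 2
        ref[1, :2] = 2
        assert math.isclose(dice_per_image(pred, ref, 2), 2 / 3)

    def test_both_empty_defined_as_one(self):
        z = np.zeros((2, 2), int)
        assert dice_per_image(z, z, 5) == 1.0


class TestRocAuc:
    def test_perfect_separation_scores_one(self):
        probs = np.stack([np.array([0.1, 0.2, 0.8, 0.9]),
                          np.array([0.9, 0.8, 0.2, 0.1])]).reshape(2, 4, 1)
        ref = np.array([1, 1, 0, 0]).reshape(4, 1)
        auc = roc_auc_ovr(probs, ref)
        assert auc[0] == 1.0 and auc[1] == 1.0

    def test_constant_scores_are_chance(self):
        probs = np.full((2, 10, 1), 0.5)
        ref = np.array([0, 1] * 5).reshape(10, 1)
        auc = roc_auc_ovr(probs, ref)
        assert math.isclose(auc[0], 0.5) and math.isclose(auc[1], 0.5)

    def test_hand_enumerated_pair_counting(self):
        """Scores (.9,.8,.4,.3), labels (1,0,1,0) -> 3 of 4 pairs concordant."""
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        probs = np.stack([1 - scores, scores]).reshape(2, 4, 1)
        ref = np.array([1, 0, 1, 0]).reshape(4, 1)
        assert math.isclose(roc_auc_ovr(probs, ref)[1], 0.75)

    def test_single_class_reference_reported_missing(self):
        probs = np.random.default_rng(0).dirichlet(np.ones(3), size=8).T
        ref = np.zeros(8, dtype=int)
        auc = roc_auc_ovr(probs.reshape(3, 8), ref)
        assert auc[1] is None and auc[2] is None
        assert auc[0] is None  # no negatives for class 0 either

    def test_matches_pair_counting_oracle_with_ties(self, rng):
        """Threshold-sweep AUC equals Mann-Whitney pair counting, <=200 px."""
        for n in (20, 100, 200):
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            probs = np.stack([1 - scores, scores])
            got = roc_auc_ovr(probs.reshape(2, n), labels)[1]
            assert math.isclose(got, pairwise_auc(scores, labels), abs_tol=1e-12)

    def test_matches_sklearn_reference(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.uniform(size=150)
        labels = rng.integers(0, 2, size=150)
        labels[0], labels[1] = 0, 1
        probs = np.stack([1 - scores, scores])
        got = roc_auc_ovr(probs.reshape(2, 150), labels)[1]
        assert math.isclose(got, roc_auc_score(labels, scores), abs_tol=1e-12)


class TestPairedTTest:
    def test_hand_computed_differences(self):
        """d = (1,2,3): t = 2 sqrt(3) ~ 3.4641 with df = 2."""
        b = np.array([1.0, 2.0, 3.0])
        a = b + np.array([1.0, 2.0, 3.0])
        t, p = paired_t_test(a, b)
        assert math.isclose(t, 2.0 * math.sqrt(3.0), rel_tol=1e-9)
        assert math.isclose(p, 2 * stats.t.sf(t, df=2), rel_tol=1e-12)

    def test_matches_scipy_reference(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        t, p = paired_t_test(a, b)
        ref = stats.ttest_rel(a, b)
        assert math.isclose(t, ref.statistic, rel_tol=1e-10)
        assert math.isclose(p, ref.pvalue, rel_tol=1e-10)

    def test_swapping_negates_t_keeps_p(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        t1, p1 = paired_t_test(a, b)
        t2, p2 = paired_t_test(b, a)
        assert math.isclose(t1, -t2, rel_tol=1e-12)
        assert math.isclose(p1, p2, rel_tol=1e-12)

    def test_zero_variance_raises_typed_error(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ZeroVarianceError):
            paired_t_test(a, a + 0.5)

    def test_constant_offset_with_jitter_is_fine(self):
        b = np.array([0.70, 0.71, 0.69, 0.72, 0.70])
        a = b + 0.01 + np.array([1e-4, -1e-4, 2e-4, -2e-4, 0.0])
        t, p = paired_t_test(a, b)
        assert t > 0 and 0 < p < 1


class TestAggregateRuns:
    def _report(self, miou):
        return MetricsReport(miou=miou, acc=0.9, f1=0.8, mean_recall=0.8,
                             precision=0.8, dice=0.8, specificity=0.9,
                             per_class={})

    def test_identical_reports_have_zero_std(self):
        agg = aggregate_runs([self._report(0.7)] * 3)
        assert math.isclose(agg["miou"][0], 0.7, rel_tol=1e-12)
        assert agg["miou"][1] < 1e-15

    def test_hand_computed_mean_and_std(self):
        agg = aggregate_runs([self._report(0.5), self._report(0.7)])
        mean, std = agg["miou"]
        assert math.isclose(mean, 0.6)
        assert math.isclose(std, math.sqrt(0.02), rel_tol=1e-9)

    def test_permutation_invariant(self, rng):
        reports = [self._report(v) for v in (0.4, 0.9, 0.6)]
        agg1 = aggregate_runs(reports)
        agg2 = aggregate_runs(reports[::-1])
        assert agg1 == agg2

    def test_single_report_rejected(self):
        with pytest.raises(ValueError, match="two runs"):
            aggregate_runs([self._report(0.5)])
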