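"""Evaluation metrics against hand counts and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from histodiff.mask_codec import LabelMask
from histodiff.metrics import (EvalCounts, accuracy, binomial_ci, confusion_counts,
                               dice, iou, mean_foreground_iou, pr_auc,
                               segmentation_report)


def brute_force_pr_auc(scores, labels):
    """Independent PR-AUC oracle: enumerate every threshold partition and
    accumulate precision·Δrecall (step-wise interpolation)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for thr in sorted(set(scores), reverse=True):
        pred = scores >= thr
        tp = int(np.sum(pred & (labels == 1)))
        fp = int(np.sum(pred & (labels == 0)))
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += precision * (recall - prev_recall)
        prev_recall = recall
    return area


class TestConfusionCounts:
    def _mask(self, arr, K=2):
        return LabelMask(labels=np.asarray(arr), K=K)

    def test_perfect_agreement(self):
        m = self._mask([[0, 1], [1, 0]])
        c = confusion_counts(m, m, 1)
        assert (c.fp, c.fn) == (0, 0) and c.tp == 2 and c.tn == 2

    def test_complement(self):
        t = self._mask([[0, 1], [1, 0]])
        p = self._mask([[1, 0], [0, 1]])
        c = confusion_counts(p, t, 1)
        assert (c.tp, c.tn) == (0, 0)

    def test_hand_enumerated_2x2(self):
        # truth has three class-1 pixels, prediction two, one overlapping
        truth = self._mask([[1, 1], [1, 0]])
        pred = self._mask([[1, 0], [0, 1]])
        c = confusion_counts(pred, truth, 1)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 2, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(self._mask([[0]]), self._mask([[0, 1]]), 0)


class TestOverlapMetrics:
    def test_iou_value(self):
        assert iou(EvalCounts(3, 1, 1, 10)) == pytest.approx(0.6)

    def test_dice_value(self):
        assert dice(EvalCounts(3, 1, 1, 10)) == pytest.approx(0.75)

    def test_perfect_and_disjoint(self):
        assert iou(EvalCounts(5, 0, 0, 5)) == 1.0
        assert iou(EvalCounts(0, 2, 3, 5)) == 0.0

    def test_empty_class_convention(self):
        c = EvalCounts(0, 0, 0, 9)
        assert iou(c) == 1.0 and dice(c) == 1.0

    def test_accuracy(self):
        assert accuracy(EvalCounts(45, 5, 5, 45)) == pytest.approx(0.9)
        with pytest.raises(ValueError):
            accuracy(EvalCounts(0, 0, 0, 0))

    @given(st.tuples(st.integers(0, 500), st.integers(0, 500),
                     st.integers(0, 500), st.integers(0, 500)))
    @settings(max_examples=200, deadline=None)
    def test_dice_iou_identity_and_range(self, counts):
        c = EvalCounts(*counts)
        i, d = iou(c), dice(c)
        assert 0.0 <= i <= 1.0 and 0.0 <= d <= 1.0
        assert abs(d - 2 * i / (1 + i)) < 1e-12


class TestBinomialCI:
    def test_normal_approximation_value(self):
        lo, hi = binomial_ci(0.9, 100)
        assert lo == pytest.approx(0.8412, abs=2e-4)
        assert hi == pytest.approx(0.9588, abs=2e-4)

    def test_clipped_at_one(self):
        lo, hi = binomial_ci(1.0, 50)
        assert hi == 1.0 and lo <= 1.0

    def test_width_shrinks_with_n(self):
        w = [binomial_ci(0.8, n)[1] - binomial_ci(0.8, n)[0] for n in (10, 100, 10000)]
        assert w[0] > w[1] > w[2]

    def test_symmetric_about_accuracy(self):
        lo, hi = binomial_ci(0.6, 200)
        assert (0.6 - lo) == pytest.approx(hi - 0.6)

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(0.5, 10, level=1.5)

    def test_wilson_flag(self):
        lo, hi = binomial_ci(0.9, 100, method="wilson")
        assert 0.8 < lo < 0.9 < hi < 1.0


class TestPrAuc:
    def test_perfect_ranking(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        labels = [1, 0, 0, 1, 0, 0, 0, 0, 1, 0]
        scores = [0.5] * 10
        want = brute_force_pr_auc(scores, labels)
        assert want == pytest.approx(0.3)
        assert pr_auc(scores, labels) == pytest.approx(want)

    def test_reversed_ranking_is_worse(self):
        good = pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        bad = pr_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert bad < good

    def test_matches_brute_force_on_random_data(self):
        r = np.random.default_rng(8)
        for _ in range(20):
            scores = np.round(r.random(12), 2)  # ties likely
            labels = r.integers(0, 2, 12)
            if labels.sum() == 0:
                labels[0] = 1
            assert pr_auc(scores, labels) == pytest.approx(
                brute_force_pr_auc(scores, labels), abs=1e-12)

    def test_monotone_transform_invariance(self):
        r = np.random.default_rng(9)
        scores = r.random(30)
        labels = r.integers(0, 2, 30)
        labels[0] = 1
        assert pr_auc(scores, labels) == pytest.approx(
            pr_auc(np.exp(3 * scores), labels))

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.5, 0.5], [0, 0])


def test_segmentation_report_pools_counts():
    a = LabelMask(labels=np.array([[0, 1], [1, 2]]), K=3)
    b = LabelMask(labels=np.array([[0, 1], [2, 2]]), K=3)
    report = segmentation_report([a], [b], 3)
    assert len(report["per_class"]) == 3
    assert report["per_class"][1]["tp"] == 1  # top-right pixel
    fg = mean_foreground_iou([a], [b], 3)
    assert 0.0 <= fg <= 1.0


def test_multi_run_summary_reports_max_and_mean():
    from histodiff.metrics import multi_run_summary
    s = multi_run_summary([0.8, 0.9, 0.7])
    assert s["max"] == 0.9 and s["mean"] == pytest.approx(0.8)
    assert s["runs"] == [0.8, 0.9, 0.7]
    with pytest.raises(ValueError):
        multi_run_summary([])
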