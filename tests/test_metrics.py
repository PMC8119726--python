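"""Contingency counting, scalar indices, curves, and aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmmnet.metrics import (
    ContingencyCounts,
    aggregate,
    contingency,
    roc_pr_curves,
    scalar_metrics,
)

tables = st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0)


def auc_pairwise_oracle(scores, labels):
    """Mann-Whitney: fraction of (pos, neg) pairs ranked correctly."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestContingency:
    def test_perfect_prediction(self, rng):
        gt = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        c = contingency(gt, gt)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == gt.sum() and c.total == gt.size

    def test_inverted_prediction(self, rng):
        gt = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        c = contingency(1 - gt, gt)
        assert c.tp == 0 and c.tn == 0

    def test_hand_built_4x4_by_enumeration(self):
        pred = np.array([[1, 1, 0, 0]] * 4)
        gt = np.array([[1, 0, 1, 0]] * 4)
        c = contingency(pred, gt)
        # exhaustive pixel walk
        tp = fp = tn = fn = 0
        for p, g in zip(pred.ravel(), gt.ravel()):
            tp += p and g
            fp += p and not g
            tn += (not p) and (not g)
            fn += (not p) and g
        assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn) == (4, 4, 4, 4)

    def test_roi_restricts_counts(self):
        pred = np.ones((4, 4))
        gt = np.zeros((4, 4))
        roi = np.zeros((4, 4))
        roi[0] = 1
        assert contingency(pred, gt, roi=roi).total == 4

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            contingency(np.zeros((2, 2)), np.zeros((3, 3)))


class TestScalarMetrics:
    def test_perfect_prediction_scores_100(self):
        m = scalar_metrics(ContingencyCounts(tp=10, fp=0, tn=20, fn=0))
        for key in ("SEN", "SPE", "ACC", "DSC", "JAC", "MCC"):
            assert m[key] == pytest.approx(100.0)

    def test_worked_example_against_sum_oracle(self):
        # TP=3, FP=1, FN=1, TN=11
        m = scalar_metrics(ContingencyCounts(tp=3, fp=1, tn=11, fn=1))
        assert m["DSC"] == pytest.approx(75.0)
        assert m["JAC"] == pytest.approx(60.0)
        assert m["SEN"] == pytest.approx(75.0)
        assert m["ACC"] == pytest.approx(100 * 14 / 16)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    @settings(deadline=None, max_examples=100)
    @given(t=tables)
    def test_dsc_jac_identity_and_ranges(self, t):
        tp, fp, tn, fn = t
        m = scalar_metrics(ContingencyCounts(tp, fp, tn, fn))
        if m["JAC"] > 0:
            assert m["DSC"] == pytest.approx(
                2 * m["JAC"] / (1 + m["JAC"] / 100.0), rel=1e-9)
        for key in ("SEN", "SPE", "ACC", "DSC", "JAC"):
            assert 0.0 <= m[key] <= 100.0
        assert -100.0 <= m["MCC"] <= 100.0

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    @settings(deadline=None, max_examples=50)
    @given(t=tables)
    def test_label_swap_permutes_sen_spe(self, t):
        tp, fp, tn, fn = t
        m = scalar_metrics(ContingencyCounts(tp, fp, tn, fn))
        swapped = scalar_metrics(ContingencyCounts(tn, fn, tp, fp))
        assert m["SEN"] == pytest.approx(swapped["SPE"])
        assert m["ACC"] == pytest.approx(swapped["ACC"])
        assert abs(m["MCC"]) == pytest.approx(abs(swapped["MCC"]), abs=1e-9)

    def test_degenerate_denominator_warns_and_returns_zero(self):
        with pytest.warns(RuntimeWarning, match="degenerate"):
            m = scalar_metrics(ContingencyCounts(tp=0, fp=0, tn=5, fn=0))
        assert m["SEN"] == 0.0


class TestCurves:
    def test_perfect_scores_give_auc_one(self):
        gt = np.array([[0, 0, 1, 1]] * 2)
        out = roc_pr_curves(gt.astype(float), gt)
        assert out["auc"] == pytest.approx(1.0)

    def test_random_scores_near_chance(self, rng):
        gt = (rng.random(4000) > 0.5).astype(int)
        scores = rng.random(4000)
        assert roc_pr_curves(scores, gt)["auc"] == pytest.approx(0.5, abs=0.05)

    def test_toy_vector_matches_pairwise_oracle(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.3])
        labels = np.array([0, 0, 1, 1, 1, 0])
        out = roc_pr_curves(scores, labels)
        assert out["auc"] == pytest.approx(auc_pairwise_oracle(scores, labels))

    def test_single_class_gt_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            roc_pr_curves(np.random.rand(8), np.zeros(8, dtype=int))


class TestAggregate:
    def test_uniform_weights_give_plain_mean(self):
        items = [{"DSC": 80.0}, {"DSC": 90.0}]
        assert aggregate(items)["weighted_mean"]["DSC"] == pytest.approx(85.0)

    def test_single_item_is_itself(self):
        assert aggregate([{"DSC": 72.5}])["weighted_mean"]["DSC"] == 72.5

    def test_weighted_mean_1_to_3(self):
        items = [{"JAC": 60.0}, {"JAC": 80.0}]
        out = aggregate(items, weights=[1, 3])
        assert out["weighted_mean"]["JAC"] == pytest.approx(
            (1 * 60.0 + 3 * 80.0) / 4)

    def test_per_item_distributions_emitted(self):
        out = aggregate([{"MCC": 10.0}, {"MCC": 30.0}], weights=[2, 2])
        assert out["per_item"]["MCC"] == [10.0, 30.0]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            aggregate([{"DSC": 1.0}], weights=[1, 2])
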