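import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from busseg.metrics import (
    ConfusionCounts,
    REPORT_COLUMNS,
    auc_curves,
    confusion,
    dice_coefficient,
    dice_loss,
    evaluate_masks,
    iou,
    mean_iou,
    scalar_metrics,
)

import oracles

binary_mask = arrays(np.uint8, (8, 8), elements=st.integers(0, 1))


class TestDice:
    def test_perfect_overlap(self):
        x = np.ones((4, 4), dtype=np.uint8)
        assert dice_coefficient(x, x) == 1.0

    def test_disjoint_masks(self):
        x = np.zeros((2, 2), dtype=np.uint8); x[0, 0] = 1
        y = np.zeros((2, 2), dtype=np.uint8); y[1, 1] = 1
        s = 1.0
        assert dice_coefficient(x, y, smooth=s) == pytest.approx(s / (2 + s))

    def test_hand_count_2x2(self):
        x = np.ones((2, 2), dtype=np.uint8)
        y = np.zeros((2, 2), dtype=np.uint8); y[0, 0] = 1
        assert dice_coefficient(x, y, smooth=1e-9) == pytest.approx(0.4, abs=1e-6)

    def test_loss_plus_dice_is_one(self, rng):
        x = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        y = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        assert dice_loss(x, y) + dice_coefficient(x, y) == 1.0

    def test_symmetric(self, rng):
        x = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        y = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        assert dice_coefficient(x, y) == dice_coefficient(y, x)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice_coefficient(np.zeros((2, 2)), np.zeros((3, 3)))


class TestConfusion:
    def test_identical_masks(self, rng):
        x = (rng.random((5, 5)) > 0.5).astype(np.uint8)
        c = confusion(x, x)
        assert c.fp == 0 and c.fn == 0
        assert c.tp == int(x.sum())

    def test_hand_counted_3x3(self):
        gold = np.zeros((3, 3), dtype=np.uint8)
        gold[0, 0] = gold[0, 1] = gold[1, 0] = gold[1, 1] = 1
        pred = np.zeros((3, 3), dtype=np.uint8)
        pred[0, 0] = pred[0, 1] = pred[1, 0] = 1   # 3 of the 4 lesion pixels
        pred[2, 2] = 1                             # 1 background pixel
        c = confusion(gold, pred)
        assert (c.tp, c.fp, c.fn, c.tn) == (3, 1, 1, 4)

    def test_counts_partition_pixels(self, rng):
        x = (rng.random((7, 7)) > 0.3).astype(np.uint8)
        y = (rng.random((7, 7)) > 0.7).astype(np.uint8)
        assert confusion(x, y).total == 49

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            confusion(np.full((2, 2), 2), np.zeros((2, 2)))


class TestScalarMetrics:
    def test_hand_counted_values(self):
        m = scalar_metrics(ConfusionCounts(tp=3, fp=1, fn=1, tn=4))
        assert m["acc"] == pytest.approx(7 / 9)
        assert m["pc"] == pytest.approx(3 / 4)
        assert m["sen"] == pytest.approx(3 / 4)
        assert m["sp"] == pytest.approx(4 / 5)
        assert m["f1"] == pytest.approx(3 / 4)

    def test_perfect_prediction(self):
        m = scalar_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=20))
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_zero_convention(self):
        m = scalar_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert m["pc"] == 0.0 and m["f1"] == 0.0

    def test_loop_oracle_100_trials(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            gold = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
            pred = (rng.random((16, 16)) > rng.random()).astype(np.uint8)
            tp, fp, fn, tn = oracles.confusion_loop(gold, pred)
            c = confusion(gold, pred)
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            m = scalar_metrics(c)
            assert m["acc"] == pytest.approx((tp + tn) / 256)
            if tp + fp:
                assert m["pc"] == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert m["sen"] == pytest.approx(tp / (tp + fn))
            if tn + fp:
                assert m["sp"] == pytest.approx(tn / (tn + fp))


class TestIou:
    def test_identical_pairs(self, rng):
        x = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        assert mean_iou([(x, x), (x, x)]) == 1.0

    def test_single_pair_equals_iou(self, rng):
        x = (rng.random((4, 4)) > 0.4).astype(np.uint8)
        y = (rng.random((4, 4)) > 0.6).astype(np.uint8)
        assert mean_iou([(x, y)]) == iou(x, y)

    def test_hand_built_mean(self):
        a = np.ones((2, 2), dtype=np.uint8)
        half = np.zeros((2, 2), dtype=np.uint8); half[0] = 1  # IOU 0.5
        assert mean_iou([(a, a), (a, half)]) == pytest.approx(0.75)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_iou([])

    @given(x=binary_mask, y=binary_mask)
    @settings(max_examples=50, deadline=None)
    def test_dice_iou_identity(self, x, y):
        # DC = 2*IOU / (1 + IOU) for the unsmoothed quantities
        if not (x.sum() or y.sum()):
            return
        i = iou(x, y)
        dc = dice_coefficient(x, y, smooth=1e-12)
        assert dc == pytest.approx(2 * i / (1 + i), abs=1e-6)
        assert i <= dc + 1e-9


class TestAuc:
    def test_perfect_scores(self, rng):
        gold = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        roc, pr = auc_curves([gold], [gold.astype(float)])
        assert roc == 1.0 and pr == 1.0

    def test_constant_scores_is_chance(self, rng):
        gold = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        roc, _ = auc_curves([gold], [np.full((8, 8), 0.5)])
        assert roc == pytest.approx(0.5)

    def test_eight_pixel_threshold_sweep(self):
        gold = np.array([[1, 1, 0, 0], [1, 0, 0, 1]], dtype=np.uint8)
        prob = np.array([[0.9, 0.6, 0.4, 0.3], [0.8, 0.55, 0.2, 0.1]])
        roc, _ = auc_curves([gold], [prob])
        expected = oracles.roc_auc_threshold_sweep(gold, prob)
        assert roc == pytest.approx(expected, abs=1e-9)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single-class"):
            auc_curves([np.zeros((4, 4), dtype=np.uint8)],
                       [np.random.default_rng(0).random((4, 4))])


class TestEvaluateMasks:
    def test_report_scores_in_unit_interval(self, rng):
        gold = [(rng.random((16, 16)) > 0.6).astype(np.uint8)
                for _ in range(4)]
        prob = [rng.random((16, 16)) for _ in range(4)]
        report = evaluate_masks(gold, prob)
        for v in report.to_row().values():
            assert 0.0 <= v <= 1.0

    def test_loss_complement_exact(self, rng):
        gold = [(rng.random((16, 16)) > 0.6).astype(np.uint8)]
        prob = [rng.random((16, 16))]
        report = evaluate_masks(gold, prob)
        assert report.loss + report.dc == 1.0

    def test_column_order(self):
        assert REPORT_COLUMNS == ("Loss", "Acc", "DC", "Sen", "Sp", "F1",
                                  "Pc", "M-IOU", "AUC")

    def test_perfect_prediction(self, rng):
        gold = [(rng.random((8, 8)) > 0.5).astype(np.uint8) for _ in range(3)]
        report = evaluate_masks(gold, [g.astype(float) for g in gold])
        assert report.dc > 0.99 and report.acc == 1.0 and report.m_iou == 1.0
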