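"""Loss and metric oracles: hand-computed cases, recount equivalence,
Dice >= Jaccard, and loss monotonicity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mbsnet import autograd as ag
from mbsnet.loss_metrics import (ConfusionCounts, LossConfig, bce_dice_loss,
                                 binarize, confusion_counts, evaluate_dataset,
                                 metrics_from_counts)


class TestBceDiceLoss:
    def test_four_pixel_hand_case(self):
        # target (1,1,0,0), p = 0.5 everywhere, eps = 1:
        # BCE = ln 2; Dice = 1 - (2*1+1)/(2+2+1) = 0.4; L = 0.5*ln2 + 0.4
        logits = np.zeros((1, 1, 2, 2), dtype=np.float32)
        target = np.array([1, 1, 0, 0], dtype=np.float32).reshape(1, 1, 2, 2)
        loss = bce_dice_loss(logits, target).item()
        assert loss == pytest.approx(0.5 * np.log(2) + 0.4, abs=1e-5)
        assert loss == pytest.approx(0.74657, abs=1e-4)

    def test_perfect_prediction_limit(self):
        target = np.array([1, 0, 1, 0], dtype=np.float32).reshape(1, 1, 2, 2)
        logits = (target * 2 - 1) * 20.0
        assert bce_dice_loss(logits, target).item() < 1e-2

    def test_weight_coefficients(self):
        # doubling only the BCE weight adds exactly one extra BCE term
        logits = np.zeros((1, 1, 2, 2), dtype=np.float32)
        target = np.array([1, 1, 0, 0], dtype=np.float32).reshape(1, 1, 2, 2)
        base = bce_dice_loss(logits, target, LossConfig()).item()
        heavy = bce_dice_loss(logits, target,
                              LossConfig(bce_weight=1.5)).item()
        assert heavy - base == pytest.approx(np.log(2), abs=1e-5)

    def test_non_binary_target_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bce_dice_loss(np.zeros((1, 1, 2, 2), np.float32),
                          np.full((1, 1, 2, 2), 0.5, np.float32))

    def test_monotone_along_line_toward_target(self, rng):
        # moving predicted probabilities linearly toward the target never
        # increases the loss
        for _ in range(5):
            target = (rng.random((1, 1, 4, 4)) > 0.5).astype(np.float32)
            p0 = rng.uniform(0.05, 0.95, size=target.shape)
            losses = []
            for lam in np.linspace(0, 0.95, 8):
                p = (1 - lam) * p0 + lam * target
                p = np.clip(p, 1e-4, 1 - 1e-4)
                logits = np.log(p / (1 - p)).astype(np.float32)
                losses.append(bce_dice_loss(logits, target).item())
            assert all(b <= a + 1e-6 for a, b in zip(losses, losses[1:]))

    def test_gradient_near_zero_at_target(self):
        target = np.array([1, 0, 0, 1], dtype=np.float32).reshape(1, 1, 2, 2)
        logits = ag.Tensor((target * 2 - 1) * 15.0, requires_grad=True)
        bce_dice_loss(logits, target).backward()
        assert np.max(np.abs(logits.grad)) < 1e-3

    def test_loss_bounded_below_by_zero(self, rng):
        for _ in range(10):
            target = (rng.random((1, 1, 4, 4)) > 0.5).astype(np.float32)
            logits = rng.normal(scale=3, size=target.shape).astype(np.float32)
            assert bce_dice_loss(logits, target).item() >= 0.0


class TestBinarize:
    def test_boundary_conventions(self):
        probs = np.array([0.5, 0.499, 0.0, 1.0])
        np.testing.assert_array_equal(binarize(probs), [1, 0, 0, 1])

    def test_all_zero_map_empty_mask(self):
        assert binarize(np.zeros((4, 4))).sum() == 0


class TestConfusionCounts:
    def test_four_pixel_enumeration(self):
        c = confusion_counts(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 1, 1, 1)

    def test_identical_masks_no_errors(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(m, m)
        assert c.fp == c.fn == 0

    def test_inverted_prediction(self, rng):
        m = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        c = confusion_counts(1 - m, m)
        assert c.tp == 0 and c.tn == 0

    def test_counts_sum_to_pixels(self, rng):
        a = (rng.random((6, 7)) > 0.3).astype(np.uint8)
        b = (rng.random((6, 7)) > 0.7).astype(np.uint8)
        assert confusion_counts(a, b).total == 42

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)))


class TestMetricsFromCounts:
    def test_four_pixel_case(self):
        m = metrics_from_counts(ConfusionCounts(tp=1, fp=1, tn=1, fn=1))
        assert m["IOU"] == pytest.approx(33.33, abs=0.01)
        assert m["F1"] == pytest.approx(50.0)
        assert m["Gmean"] == pytest.approx(50.0)

    def test_perfect_mask_scores_100(self):
        m = metrics_from_counts(ConfusionCounts(tp=10, fp=0, tn=10, fn=0))
        assert all(m[k] == 100.0 for k in ("IOU", "F1", "Precision", "Recall",
                                           "Specificity", "Gmean"))

    def test_degenerate_conventions(self):
        both_empty = metrics_from_counts(ConfusionCounts(tp=0, fp=0, tn=4, fn=0))
        assert both_empty["IOU"] == 100.0 and both_empty["empty_pair"]
        false_alarm = metrics_from_counts(ConfusionCounts(tp=0, fp=2, tn=2, fn=0))
        assert false_alarm["IOU"] == 0.0 and false_alarm["F1"] == 0.0
        missed = metrics_from_counts(ConfusionCounts(tp=0, fp=1, tn=2, fn=1))
        assert missed["F1"] == 0.0

    def test_recount_oracle_on_random_mask_pairs(self, rng):
        """Metric values agree exactly with a brute-force per-pixel recount."""
        for _ in range(200):
            pred = (rng.random((5, 5)) > rng.random()).astype(np.uint8)
            gt = (rng.random((5, 5)) > rng.random()).astype(np.uint8)
            c = confusion_counts(pred, gt)
            tp = sum(int(p == 1 and g == 1) for p, g in
                     zip(pred.ravel(), gt.ravel()))
            fp = sum(int(p == 1 and g == 0) for p, g in
                     zip(pred.ravel(), gt.ravel()))
            fn = sum(int(p == 0 and g == 1) for p, g in
                     zip(pred.ravel(), gt.ravel()))
            tn = 25 - tp - fp - fn
            assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
            m = metrics_from_counts(c)
            ref = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            assert m == ref

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(tp=st.integers(0, 50), fp=st.integers(0, 50),
           fn=st.integers(0, 50), tn=st.integers(0, 50))
    def test_f1_dominates_iou(self, tp, fp, fn, tn):
        """Dice coefficient >= Jaccard index for every confusion table."""
        if tp + fp + fn == 0:
            return
        m = metrics_from_counts(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
        assert m["F1"] >= m["IOU"] - 1e-9


class TestEvaluateDataset:
    def test_single_image_mean_equals_image(self, rng):
        pred = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        gt = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        report = evaluate_dataset([pred], [gt])
        assert report.mean == {k: report.per_image[0][k]
                               for k in report.mean}

    def test_duplication_invariance(self, rng):
        pred = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        gt = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        once = evaluate_dataset([pred], [gt]).mean
        thrice = evaluate_dataset([pred] * 3, [gt] * 3).mean
        assert once == pytest.approx(thrice)

    def test_macro_average_of_extremes(self):
        perfect = np.ones((4, 4), dtype=np.uint8)
        wrong = np.zeros((4, 4), dtype=np.uint8)
        gt = np.ones((4, 4), dtype=np.uint8)
        report = evaluate_dataset([perfect, wrong], [gt, gt])
        assert report.mean["IOU"] == pytest.approx(50.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            evaluate_dataset([], [])

    def test_csv_export(self, tmp_path, rng):
        pred = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        gt = (rng.random((4, 4)) > 0.5).astype(np.uint8)
        report = evaluate_dataset([pred], [gt], names=["a.png"])
        out = tmp_path / "metrics.csv"
        report.to_csv(out)
        lines = out.read_text().strip().splitlines()
        assert lines[0].startswith("image,IOU,F1")
        assert lines[1].startswith("a.png") and lines[-1].startswith("MEAN")
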