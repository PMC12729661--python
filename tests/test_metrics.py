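"""Overlap and boundary metrics against brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from emaseg import ValidationError
from emaseg.metrics import (ConfusionCounts, confusion_counts, hd95,
                            overlap_scores)


def brute_force_counts(pred, gt):
    tp = fp = tn = fn = 0
    for p, g in zip(pred.reshape(-1), gt.reshape(-1)):
        if p and g:
            tp += 1
        elif p and not g:
            fp += 1
        elif not p and not g:
            tn += 1
        else:
            fn += 1
    return tp, fp, tn, fn


def brute_force_hd95(pred, gt, spacing):
    """All-pairs boundary distances, pooled from both directions."""
    def boundary_pts(mask):
        er = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
        ys, xs = np.nonzero(mask & ~er)
        return np.stack([ys * spacing[0], xs * spacing[1]], 1)

    bp, bg = boundary_pts(pred.astype(bool)), boundary_pts(gt.astype(bool))
    d = np.sqrt(((bp[:, None, :] - bg[None, :, :]) ** 2).sum(-1))
    pooled = np.concatenate([d.min(1), d.min(0)])
    return float(np.percentile(pooled, 95))


class TestConfusionCounts:
    def test_hand_counted_2x2_case(self):
        pred = np.array([[1, 1], [0, 0]])
        gt = np.array([[0, 1], [0, 1]])
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 1, 1)

    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.uniform(size=(16, 16)) > 0.5).astype(np.uint8)
        c = confusion_counts(m, m)
        assert c.fp == c.fn == 0
        assert c.tp == int(m.sum())

    def test_all_ones_vs_all_zeros(self):
        pred = np.ones((8, 8), dtype=np.uint8)
        gt = np.zeros((8, 8), dtype=np.uint8)
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 64, 0, 0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            confusion_counts(np.zeros((4, 4)), np.zeros((5, 4)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_matches_per_pixel_oracle(self, seed):
        r = np.random.default_rng(seed)
        pred = r.uniform(size=(16, 16)) > 0.5
        gt = r.uniform(size=(16, 16)) > 0.5
        c = confusion_counts(pred, gt)
        assert (c.tp, c.fp, c.tn, c.fn) == brute_force_counts(pred, gt)
        assert c.total == 256


class TestOverlapScores:
    def test_hand_evaluated_unit_counts(self):
        s = overlap_scores(ConfusionCounts(1, 1, 1, 1))
        assert s.iou == pytest.approx(1 / 3)
        assert s.dsc == pytest.approx(1 / 2)
        assert s.rec == s.spe == s.pre == pytest.approx(1 / 2)

    def test_perfect_prediction_is_all_ones(self):
        s = overlap_scores(ConfusionCounts(10, 0, 22, 0))
        assert s.iou == s.dsc == s.rec == s.spe == s.pre == 1.0

    def test_dsc_iou_identity_holds_per_image(self):
        """DSC = 2 IoU / (1 + IoU) per image (it does not commute with
        averaging across subjects, which is why reported means differ)."""
        s = overlap_scores(ConfusionCounts(917, 40, 3000, 44))
        assert s.dsc == pytest.approx(2 * s.iou / (1 + s.iou), abs=1e-9)
        # the published per-image relation at IoU ~ 0.9162
        assert 2 * 0.9162 / 1.9162 == pytest.approx(0.95627, abs=1e-4)

    def test_degenerate_denominators_follow_vacuous_rule(self):
        empty_both = overlap_scores(ConfusionCounts(0, 0, 64, 0))
        assert empty_both.iou == empty_both.rec == empty_both.pre == 1.0
        missed_all = overlap_scores(ConfusionCounts(0, 0, 60, 4))
        assert missed_all.rec == 0.0 and missed_all.pre == 0.0

    def test_dilating_prediction_never_decreases_fp(self, rng):
        gt = np.zeros((20, 20), dtype=np.uint8)
        gt[5:12, 6:13] = 1
        pred = gt.copy()
        prev_fp = confusion_counts(pred, gt).fp
        for _ in range(4):
            pred = ndimage.binary_dilation(pred).astype(np.uint8)
            fp = confusion_counts(pred, gt).fp
            assert fp >= prev_fp
            prev_fp = fp


class TestHD95:
    def test_identical_masks_give_zero(self):
        m = np.zeros((20, 20), dtype=np.uint8)
        m[4:12, 5:14] = 1
        assert hd95(m, m, (0.5, 0.5)) == 0.0

    def test_two_single_pixels_5px_apart_at_half_mm(self):
        a = np.zeros((11, 11), dtype=np.uint8)
        b = np.zeros((11, 11), dtype=np.uint8)
        a[5, 2] = 1
        b[5, 7] = 1
        assert hd95(a, b, (0.5, 0.5)) == pytest.approx(2.5)

    def test_unit_translation_of_square(self):
        a = np.zeros((16, 16), dtype=np.uint8)
        b = np.zeros((16, 16), dtype=np.uint8)
        a[4:10, 4:10] = 1
        b[5:11, 4:10] = 1
        val = hd95(a, b, (1.0, 1.0))
        assert val == pytest.approx(brute_force_hd95(a, b, (1.0, 1.0)))
        assert val == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        m = np.zeros((8, 8), dtype=np.uint8)
        full = np.ones((8, 8), dtype=np.uint8)
        with pytest.raises(ValidationError):
            hd95(m, full, (1, 1))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_symmetry_and_oracle_agreement_on_random_blobs(self, seed):
        r = np.random.default_rng(seed)
        def blob():
            m = np.zeros((24, 24), dtype=np.uint8)
            y, x = r.integers(6, 18, 2)
            h, w = r.integers(3, 7, 2)
            m[y - h // 2:y + h // 2 + 1, x - w // 2:x + w // 2 + 1] = 1
            return m
        a, b = blob(), blob()
        spacing = (0.4, 0.7)
        ab = hd95(a, b, spacing)
        ba = hd95(b, a, spacing)
        assert ab == pytest.approx(ba)
        assert ab == pytest.approx(brute_force_hd95(a, b, spacing), abs=1e-9)
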