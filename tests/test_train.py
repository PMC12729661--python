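"""Hybrid loss, augmentation policy, and training-loop smoke behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from emaseg import ValidationError
from emaseg.configs import AugmentPolicy
from emaseg.configs import test_profile as make_test_profile
from emaseg.data import SplitSpec, read_manifest
from emaseg.phantom import PhantomParams, generate_dataset
from emaseg.train import LossValues, augment_sample, total_loss, train


class TestLoss:
    def test_perfect_prediction_near_zero(self):
        g = np.array([1.0, 1.0, 0.0, 0.0])
        lv = total_loss(g.copy(), g)
        assert lv.l_dice < 1e-5 and lv.l_bce < 1e-5

    def test_total_miss_dice_near_one(self):
        g = np.array([1.0, 0.0, 1.0, 0.0])
        lv = total_loss(1.0 - g, g)
        assert lv.l_dice == pytest.approx(1.0, abs=1e-4)

    def test_hand_evaluated_partial_overlap(self):
        g = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.array([1.0, 0.0, 0.0, 0.0])
        lv = total_loss(p, g)
        assert lv.l_dice == pytest.approx(1.0 - 2.0 / 3.0, abs=1e-4)

    def test_total_is_exact_sum(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.01, 0.99, 64)
        g = (rng.uniform(size=64) > 0.5).astype(float)
        lv = total_loss(p, g)
        assert lv.l_total == lv.l_dice + lv.l_bce

    def test_inconsistent_total_rejected(self):
        with pytest.raises(ValidationError):
            LossValues(l_dice=0.2, l_bce=0.3, l_total=0.6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            total_loss(np.zeros(4), np.zeros(5))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 999))
    def test_dice_permutation_invariant_over_pixels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.01, 0.99, 50)
        g = (rng.uniform(size=50) > 0.4).astype(float)
        perm = rng.permutation(50)
        assert total_loss(p, g).l_dice == pytest.approx(
            total_loss(p[perm], g[perm]).l_dice, abs=1e-12)


@pytest.fixture()
def pair(small_phantom):
    frame, mask, _ = small_phantom
    return frame, mask


class TestAugment:
    def test_zero_probabilities_are_identity(self, pair):
        frame, mask = pair
        f2, m2 = augment_sample(frame, mask, AugmentPolicy.disabled(), seed=3)
        np.testing.assert_array_equal(f2.pixels, frame.pixels)
        np.testing.assert_array_equal(m2.labels, mask.labels)

    def test_deterministic_given_seed(self, pair):
        frame, mask = pair
        policy = AugmentPolicy()
        a = augment_sample(frame, mask, policy, seed=11)
        b = augment_sample(frame, mask, policy, seed=11)
        np.testing.assert_array_equal(a[0].pixels, b[0].pixels)
        np.testing.assert_array_equal(a[1].labels, b[1].labels)

    def test_right_angle_rotation_preserves_mask_pixel_count(self, pair):
        # at exact right angles the nearest-resampled warp is a pixel
        # permutation, so the foreground count is invariant
        from emaseg.train import _geometric_warp
        _, mask = pair
        rot = _geometric_warp(mask.labels.astype(float), 0, 90.0, 1.0, None)
        assert rot.sum() == mask.labels.sum()

    def test_geometry_stays_paired_and_mask_binary(self, pair):
        frame, mask = pair
        policy = AugmentPolicy(rotation_prob=1.0, scale_prob=1.0, elastic_prob=1.0,
                               brightness_prob=0, contrast_prob=0, noise_prob=0)
        f2, m2 = augment_sample(frame, mask, policy, seed=5)
        assert f2.shape == frame.shape and m2.shape == mask.shape
        assert set(np.unique(m2.labels)) <= {0, 1}
        # the warped mask must still overlap the original substantially
        inter = (m2.labels & mask.labels).sum()
        assert inter > 0.2 * mask.labels.sum()

    def test_intensity_transforms_do_not_touch_mask(self, pair):
        frame, mask = pair
        policy = AugmentPolicy(rotation_prob=0, scale_prob=0, elastic_prob=0,
                               brightness_prob=1.0, contrast_prob=1.0, noise_prob=1.0)
        f2, m2 = augment_sample(frame, mask, policy, seed=7)
        np.testing.assert_array_equal(m2.labels, mask.labels)
        assert not np.array_equal(f2.pixels, frame.pixels)
        assert f2.pixels.min() >= 0.0 and f2.pixels.max() <= 1.0


@pytest.fixture(scope="module")
def tiny_manifest(tmp_path_factory):
    out = tmp_path_factory.mktemp("tinydata")
    params = PhantomParams(seed=0)
    return generate_dataset(2, params, out, seed=21)


class TestTrainingLoop:
    def test_one_epoch_smoke_writes_history_and_checkpoint(self, tiny_manifest, tmp_path):
        df = read_manifest(tiny_manifest)
        ids = list(df["id"])
        split = SplitSpec(train_ids=ids, val_ids=[], test_ids=[], seed=0)
        cfg = make_test_profile(epochs=1, batch_size=2, seed=0)
        res = train(cfg, tiny_manifest, tmp_path / "run", split=split,
                    log=lambda *_: None)
        assert res.checkpoint.exists()
        hist = res.history.read_text().strip().splitlines()
        assert hist[0] == "epoch,train_loss,val_loss,val_dsc"
        assert len(hist) == 2  # header + one epoch

    def test_fixed_seed_reproduces_first_epoch_loss(self, tiny_manifest, tmp_path):
        df = read_manifest(tiny_manifest)
        ids = list(df["id"])
        split = SplitSpec(train_ids=ids, val_ids=[], test_ids=[], seed=0)
        cfg = make_test_profile(epochs=1, batch_size=2, seed=9)
        r1 = train(cfg, tiny_manifest, tmp_path / "a", split=split, log=lambda *_: None)
        r2 = train(cfg, tiny_manifest, tmp_path / "b", split=split, log=lambda *_: None)
        h1 = r1.history.read_text()
        h2 = r2.history.read_text()
        assert h1 == h2

    def test_empty_training_split_rejected(self, tiny_manifest, tmp_path):
        split = SplitSpec(train_ids=[], val_ids=[], test_ids=[], seed=0)
        with pytest.raises(ValidationError):
            train(make_test_profile(epochs=1), tiny_manifest, tmp_path / "x", split=split)
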