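"""Frame/mask I/O, preprocessing and dataset splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from PIL import Image

from emaseg import IOErrorEmaseg, ValidationError
from emaseg.data import (BinaryMask, UltrasoundFrame, load_frame, load_mask,
                         preprocess, read_manifest, resize_mask, split_dataset,
                         write_manifest, write_mask)


def _write_png(path, arr):
    Image.fromarray(arr.astype(np.uint8)).save(path)


class TestLoadFrame:
    def test_saturated_and_black_images_normalize_to_unit_range(self, tmp_path):
        white = tmp_path / "white.png"
        black = tmp_path / "black.png"
        _write_png(white, np.full((40, 50), 255))
        _write_png(black, np.zeros((40, 50)))
        fw = load_frame(white, (0.5, 0.5))
        fb = load_frame(black, (0.5, 0.5))
        assert fw.pixels.max() == fw.pixels.min() == 1.0
        assert fb.pixels.max() == fb.pixels.min() == 0.0
        assert fw.id == "white"

    def test_wide_source_keeps_row_col_convention(self, tmp_path):
        # a 730 x 660 (W x H) still loads as H=660 rows, W=730 cols
        p = tmp_path / "wide.jpg"
        Image.fromarray(np.zeros((660, 730), dtype=np.uint8)).save(p)
        frame = load_frame(p, (0.3, 0.3))
        assert frame.shape == (660, 730)

    def test_rgb_is_luminance_converted(self, tmp_path):
        p = tmp_path / "rgb.png"
        arr = np.zeros((40, 40, 3), dtype=np.uint8)
        arr[..., 0] = 255  # pure red
        Image.fromarray(arr).save(p)
        frame = load_frame(p, (1, 1))
        assert frame.pixels.ndim == 2
        assert 0.0 < frame.pixels.mean() < 1.0

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(IOErrorEmaseg):
            load_frame(tmp_path / "nope.png", (1, 1))

    def test_frame_invariants_enforced(self):
        with pytest.raises(ValidationError):
            UltrasoundFrame(pixels=np.zeros((8, 8)), spacing_mm=(1, 1), id="tiny")
        with pytest.raises(ValidationError):
            UltrasoundFrame(pixels=np.full((64, 64), 2.0), spacing_mm=(1, 1), id="hot")
        with pytest.raises(ValidationError):
            UltrasoundFrame(pixels=np.zeros((64, 64)), spacing_mm=(0, 1), id="flat")


class TestMaskRoundTrip:
    def test_write_then_load_reproduces_labels_exactly(self, tmp_path, rng):
        labels = (rng.uniform(size=(64, 48)) > 0.6).astype(np.uint8)
        mask = BinaryMask(labels=labels, id="m")
        path = write_mask(mask, tmp_path / "m.png")
        back = load_mask(path)
        np.testing.assert_array_equal(back.labels, labels)

    def test_threshold_at_128(self, tmp_path):
        arr = np.array([[0, 127, 128, 255]], dtype=np.uint8).repeat(40, 0)
        arr = np.tile(arr, (1, 10))
        _write_png(tmp_path / "t.png", arr)
        m = load_mask(tmp_path / "t.png")
        np.testing.assert_array_equal(np.unique(m.labels), [0, 1])
        assert m.labels[0, 0] == 0 and m.labels[0, 2] == 1

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValidationError):
            BinaryMask(labels=np.full((40, 40), 3), id="bad")


class TestPreprocess:
    def test_identity_when_already_target_size(self):
        f = UltrasoundFrame(pixels=np.random.default_rng(0).uniform(0, 1, (512, 512)),
                            spacing_mm=(0.2, 0.2), id="x")
        out = preprocess(f, 512)
        np.testing.assert_array_equal(out.pixels, f.pixels)

    def test_spacing_rescaled_preserves_physical_extent(self):
        f = UltrasoundFrame(pixels=np.zeros((660, 730), dtype=np.float32),
                            spacing_mm=(0.2, 0.25), id="x")
        out = preprocess(f, 512)
        assert out.shape == (512, 512)
        assert out.spacing_mm[0] == pytest.approx(0.2 * 660 / 512)
        assert out.spacing_mm[1] == pytest.approx(0.25 * 730 / 512)
        # physical field of view conserved on both axes
        assert 660 * 0.2 == pytest.approx(512 * out.spacing_mm[0], rel=1e-6)
        assert 730 * 0.25 == pytest.approx(512 * out.spacing_mm[1], rel=1e-6)

    def test_constant_image_stays_constant(self):
        f = UltrasoundFrame(pixels=np.full((100, 150), 0.5, dtype=np.float32),
                            spacing_mm=(1, 1), id="c")
        out = preprocess(f, 64)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-6)

    def test_nondivisible_target_rejected(self):
        f = UltrasoundFrame(pixels=np.zeros((64, 64)), spacing_mm=(1, 1), id="x")
        with pytest.raises(ValidationError):
            preprocess(f, 100)

    def test_mask_resize_preserves_binarity(self):
        m = BinaryMask(labels=(np.arange(64 * 64).reshape(64, 64) % 7 == 0).astype(np.uint8),
                       id="m")
        out = resize_mask(m, (40, 40))
        assert set(np.unique(out.labels)) <= {0, 1}


class TestSplitDataset:
    def test_710_images_split_7_2_1(self):
        ids = [f"im{i:04d}" for i in range(710)]
        s = split_dataset(ids, (0.7, 0.2, 0.1), seed=3)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (497, 142, 71)

    def test_deterministic_given_seed(self):
        ids = [f"a{i}" for i in range(10)]
        s1 = split_dataset(ids, (0.7, 0.2, 0.1), seed=5)
        s2 = split_dataset(ids, (0.7, 0.2, 0.1), seed=5)
        assert s1 == s2

    def test_remainder_goes_to_train(self):
        s = split_dataset(["a", "b", "c"], (0.7, 0.2, 0.1), seed=0)
        assert (len(s.train_ids), len(s.val_ids), len(s.test_ids)) == (3, 0, 0)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            split_dataset(["a", "a", "b"], (0.7, 0.2, 0.1), seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(n=st.integers(1, 200), seed=st.integers(0, 1000))
    def test_split_is_a_partition(self, n, seed):
        ids = [f"id{i}" for i in range(n)]
        s = split_dataset(ids, (0.7, 0.2, 0.1), seed=seed)
        combined = sorted(s.train_ids + s.val_ids + s.test_ids)
        assert combined == sorted(ids)


def test_manifest_round_trip_resolves_relative_paths(tmp_path):
    rows = [{"id": "p1", "image_path": "images/p1.png", "mask_path": "masks/p1.png",
             "row_mm_per_px": 0.5, "col_mm_per_px": 0.4}]
    path = write_manifest(rows, tmp_path / "manifest.csv")
    df = read_manifest(path)
    assert df.loc[0, "image_path"] == str(tmp_path / "images/p1.png")
    assert df.loc[0, "row_mm_per_px"] == 0.5
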