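"""Data model, image/mask I/O, preprocessing and dataset splitting.

Conventions
-----------
* Coordinates are 0-based, row-major, origin top-left; array shapes are
  (rows=H, cols=W).  A "730 x 660" ultrasound still is W=730, H=660.
* Frames hold intensities in [0, 1] with per-axis physical pixel spacing in
  millimetres; masks are {0, 1} and serialized as {0, 255} single-channel
  PNG (read threshold 128).
* Manifests are CSV with columns ``id,image_path,mask_path,row_mm_per_px,
  col_mm_per_px``; relative paths are resolved against the manifest's
  directory.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image
from skimage.transform import resize as _sk_resize

from . import IOErrorEmaseg, ValidationError

__all__ = [
    "UltrasoundFrame",
    "BinaryMask",
    "SplitSpec",
    "load_frame",
    "load_mask",
    "write_mask",
    "write_frame",
    "preprocess",
    "resize_mask",
    "split_dataset",
    "read_manifest",
    "write_manifest",
]

MIN_SIZE = 32
MASK_THRESHOLD = 128


@dataclasses.dataclass
class UltrasoundFrame:
    """One grayscale B-mode still with physical pixel spacing."""

    pixels: np.ndarray          # (H, W) float in [0, 1]
    spacing_mm: tuple[float, float]  # (row_mm_per_px, col_mm_per_px)
    id: str

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2:
            raise ValidationError(f"frame {self.id!r}: pixels must be 2-D")
        h, w = self.pixels.shape
        if h < MIN_SIZE or w < MIN_SIZE:
            raise ValidationError(f"frame {self.id!r}: {h}x{w} below minimum {MIN_SIZE}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValidationError(f"frame {self.id!r}: intensities outside [0, 1]")
        r, c = self.spacing_mm
        if r <= 0 or c <= 0:
            raise ValidationError(f"frame {self.id!r}: spacing must be positive")
        self.spacing_mm = (float(r), float(c))

    @property
    def shape(self):
        return self.pixels.shape


@dataclasses.dataclass
class BinaryMask:
    """Per-pixel {0,1} eye-muscle labeling aligned to a frame."""

    labels: np.ndarray
    id: str

    def __post_init__(self):
        lab = np.asarray(self.labels)
        if lab.ndim != 2:
            raise ValidationError(f"mask {self.id!r}: labels must be 2-D")
        vals = np.unique(lab)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValidationError(f"mask {self.id!r}: values must be 0/1, got {vals[:5]}")
        self.labels = lab.astype(np.uint8)

    @property
    def shape(self):
        return self.labels.shape


@dataclasses.dataclass
class SplitSpec:
    """A disjoint train/val/test partition of dataset ids."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    seed: int

    def __post_init__(self):
        groups = (self.train_ids, self.val_ids, self.test_ids)
        all_ids = [i for g in groups for i in g]
        if len(set(all_ids)) != len(all_ids):
            raise ValidationError("split groups are not pairwise disjoint")


def _read_image(path) -> np.ndarray:
    path = Path(path)
    try:
        with Image.open(path) as im:
            if im.mode not in ("L", "I;16"):
                im = im.convert("L")  # ITU-R 601 luminance for RGB sources
            arr = np.asarray(im)
    except FileNotFoundError as e:
        raise IOErrorEmaseg(f"cannot read image {path}: {e}") from e
    except OSError as e:
        raise IOErrorEmaseg(f"cannot read image {path}: {e}") from e
    if arr.size == 0:
        raise ValidationError(f"zero-size image {path}")
    return arr


def load_frame(path, spacing_mm: tuple[float, float]) -> UltrasoundFrame:
    """Read an 8-bit grayscale/RGB JPEG or PNG and rescale to [0, 1]."""
    arr = _read_image(path)
    scale = 65535.0 if arr.dtype == np.uint16 else 255.0
    pixels = arr.astype(np.float32) / scale
    return UltrasoundFrame(pixels=pixels, spacing_mm=spacing_mm, id=Path(path).stem)


def load_mask(path) -> BinaryMask:
    arr = _read_image(path)
    return BinaryMask(labels=(arr >= MASK_THRESHOLD).astype(np.uint8), id=Path(path).stem)


def write_mask(mask: BinaryMask, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        Image.fromarray((mask.labels * 255).astype(np.uint8), mode="L").save(path)
    except OSError as e:
        raise IOErrorEmaseg(f"cannot write mask {path}: {e}") from e
    return path


def write_frame(frame: UltrasoundFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.round(frame.pixels * 255.0).astype(np.uint8)
    try:
        Image.fromarray(arr, mode="L").save(path)
    except OSError as e:
        raise IOErrorEmaseg(f"cannot write frame {path}: {e}") from e
    return path


def preprocess(frame: UltrasoundFrame, target: int = 512) -> UltrasoundFrame:
    """Resize to ``target x target`` (bilinear) preserving the physical field
    of view: each axis' spacing is multiplied by its resize factor."""
    if target % 32 != 0:
        raise ValidationError(f"target size {target} must be divisible by 32")
    h, w = frame.shape
    if (h, w) == (target, target):
        return frame
    pixels = _sk_resize(frame.pixels, (target, target), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
    pixels = np.clip(pixels, 0.0, 1.0).astype(np.float32)
    r, c = frame.spacing_mm
    return UltrasoundFrame(pixels=pixels,
                           spacing_mm=(r * h / target, c * w / target),
                           id=frame.id)


def resize_mask(mask: BinaryMask, shape: tuple[int, int]) -> BinaryMask:
    """Nearest-neighbour resize (preserves binarity)."""
    if mask.shape == tuple(shape):
        return mask
    lab = _sk_resize(mask.labels.astype(np.float32), shape, order=0, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return BinaryMask(labels=(lab > 0.5).astype(np.uint8), id=mask.id)


def split_dataset(ids: Sequence[str], ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
                  seed: int = 0) -> SplitSpec:
    """Random 7:2:1-style partition; sizes floor(n*ratio), remainder to train."""
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in dataset")
    if any(r <= 0 for r in ratios):
        raise ValidationError("split ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValidationError(f"split ratios must sum to 1, got {sum(ratios)}")
    n = len(ids)
    n_tr, n_va, n_te = (int(np.floor(n * r)) for r in ratios)
    n_tr += n - (n_tr + n_va + n_te)
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [ids[i] for i in order]
    return SplitSpec(train_ids=shuffled[:n_tr],
                     val_ids=shuffled[n_tr:n_tr + n_va],
                     test_ids=shuffled[n_tr + n_va:],
                     seed=seed)


MANIFEST_COLUMNS = ["id", "image_path", "mask_path", "row_mm_per_px", "col_mm_per_px"]


def write_manifest(rows: list[dict], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)
    return path


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except FileNotFoundError as e:
        raise IOErrorEmaseg(f"cannot read manifest {path}: {e}") from e
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns {missing}")
    base = path.parent

    def resolve(p):
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    df["image_path"] = df["image_path"].map(resolve)
    df["mask_path"] = df["mask_path"].map(resolve)
    return df
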