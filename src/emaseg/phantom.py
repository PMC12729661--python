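"""Synthetic B-mode-like phantoms with known masks and pixel spacing.

The longissimus cross-section is emulated as a filled, rotated superellipse
(`|u/a|^p + |v/b|^p <= 1` with exponent p in [1.5, 3]) — a bean-to-oval family
that covers the shapes seen in livestock ultrasound.  The intensity model is
deliberately low-contrast: a mid-grey tissue background, a darker muscle
interior, and a bright, partially broken echogenic rim, optionally crossed by
bright streak artifacts.  Fully developed speckle is approximated by a
multiplicative unit-mean Gamma field followed by a light Gaussian blur; this
reproduces the low-SNR regime the segmentation modules target without
acoustic wave simulation.

Every phantom is deterministic given its seed, and the paired mask/area
record give downstream stages an exact ground truth.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.special import gamma as _gamma_fn

from . import ValidationError
from .data import BinaryMask, UltrasoundFrame, write_frame, write_manifest, write_mask
from .ema import AreaRecord, Calibration, measure_area

__all__ = ["PhantomParams", "generate_phantom", "generate_dataset"]


@dataclasses.dataclass
class PhantomParams:
    """Generation ranges; defaults emulate the study's acquisition regime.

    The area span follows the reference population's descriptive statistics
    (356–1490 mm²); spacing defaults to 0.7 mm/px so the largest target still
    fits a 128-px test field (the device calibration itself is configurable,
    not fixed).
    """

    image_size: tuple[int, int] = (128, 128)
    area_range_mm2: tuple[float, float] = (356.0, 1490.0)
    axis_ratio_range: tuple[float, float] = (0.55, 0.8)
    exponent_range: tuple[float, float] = (1.5, 3.0)
    rotation_range_deg: tuple[float, float] = (-35.0, 35.0)
    feather_sigma_px: float = 1.0
    speckle_strength: float = 0.35
    rim_break_prob: float = 0.5
    artifact_count_range: tuple[int, int] = (0, 3)
    spacing_mm: tuple[float, float] = (0.7, 0.7)
    background_intensity: float = 0.45
    interior_intensity: float = 0.22
    rim_intensity: float = 0.85
    rim_width_px: float = 2.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.area_range_mm2
        if not (0 < lo <= hi):
            raise ValidationError("area range must be positive and ordered")
        if self.feather_sigma_px < 0:
            raise ValidationError("feather sigma must be >= 0")
        if self.speckle_strength < 0:
            raise ValidationError("speckle strength must be >= 0")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValidationError("spacing must be positive")


def _superellipse_area_coeff(p: float) -> float:
    """Area of |u/a|^p + |v/b|^p <= 1 equals coeff * a * b."""
    return 4.0 * _gamma_fn(1.0 + 1.0 / p) ** 2 / _gamma_fn(1.0 + 2.0 / p)


def generate_phantom(params: PhantomParams, seed: int
                     ) -> tuple[UltrasoundFrame, BinaryMask, AreaRecord]:
    """One phantom frame + exact mask + area record, deterministic in seed."""
    rng = np.random.default_rng(seed)
    H, W = params.image_size
    row_mm, col_mm = params.spacing_mm

    area = rng.uniform(*params.area_range_mm2)
    q = rng.uniform(*params.axis_ratio_range)
    p = rng.uniform(*params.exponent_range)
    theta = np.deg2rad(rng.uniform(*params.rotation_range_deg))

    k = _superellipse_area_coeff(p)
    a_mm = np.sqrt(area / (k * q))      # major semi-axis
    b_mm = q * a_mm
    field_h, field_w = H * row_mm, W * col_mm
    if 2.0 * a_mm > 0.92 * min(field_h, field_w):
        raise ValidationError(
            f"target area {area:.0f} mm2 needs extent {2 * a_mm:.1f} mm; "
            f"field is only {field_h:.1f} x {field_w:.1f} mm")

    # centre jitter keeps the whole shape inside the field
    max_dy = field_h / 2 - 1.04 * a_mm
    max_dx = field_w / 2 - 1.04 * a_mm
    cy_mm = rng.uniform(-max(max_dy, 0.0), max(max_dy, 0.0))
    cx_mm = rng.uniform(-max(max_dx, 0.0), max(max_dx, 0.0))

    yy = (np.arange(H) + 0.5) * row_mm - field_h / 2 - cy_mm
    xx = (np.arange(W) + 0.5) * col_mm - field_w / 2 - cx_mm
    Y, X = np.meshgrid(yy, xx, indexing="ij")
    u = np.cos(theta) * X + np.sin(theta) * Y
    v = -np.sin(theta) * X + np.cos(theta) * Y
    r = (np.abs(u / a_mm) ** p + np.abs(v / b_mm) ** p)
    mask = (r <= 1.0).astype(np.uint8)

    # intensity template: dark interior, bright (broken) rim, mid background
    img = np.full((H, W), params.background_intensity, dtype=np.float64)
    d_in = ndimage.distance_transform_edt(mask)
    d_out = ndimage.distance_transform_edt(1 - mask)
    rim = (d_in > 0) & (d_in <= 1.0) | ((d_out > 0) & (d_out <= params.rim_width_px))
    interior = mask.astype(bool) & ~rim
    img[interior] = params.interior_intensity
    rim_on = rim.copy()
    if params.rim_break_prob > 0 and rng.uniform() < params.rim_break_prob:
        phi = np.arctan2(Y, X)
        n_breaks = rng.integers(1, 4)
        for _ in range(n_breaks):
            centre = rng.uniform(-np.pi, np.pi)
            half_width = rng.uniform(0.1, 0.35)
            dphi = np.angle(np.exp(1j * (phi - centre)))
            rim_on &= ~(np.abs(dphi) < half_width)
    img[rim_on] = params.rim_intensity

    n_art = int(rng.integers(params.artifact_count_range[0],
                             params.artifact_count_range[1] + 1))
    for _ in range(n_art):
        # bright near-vertical streak (reverberation-like)
        x0 = rng.uniform(0, W)
        slope = rng.uniform(-0.3, 0.3)
        width = rng.uniform(0.8, 2.0)
        cols = np.arange(W)[None, :] - (x0 + slope * np.arange(H)[:, None])
        img += 0.25 * np.exp(-0.5 * (cols / width) ** 2)

    if params.feather_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.feather_sigma_px, mode="nearest")

    if params.speckle_strength > 0:
        shape_k = 1.0 / params.speckle_strength ** 2
        mult = rng.gamma(shape_k, 1.0 / shape_k, size=(H, W))
        img = img * mult
        img = ndimage.gaussian_filter(img, 0.6, mode="nearest")

    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    fid = f"phantom_{seed:08d}"
    frame = UltrasoundFrame(pixels=img, spacing_mm=params.spacing_mm, id=fid)
    mask_obj = BinaryMask(labels=mask, id=fid)
    record = measure_area(mask_obj, Calibration(row_mm, col_mm))
    return frame, mask_obj, record


def generate_dataset(n: int, params: PhantomParams, out_dir, seed: int) -> Path:
    """Write ``n`` phantom image/mask pairs plus a manifest CSV.

    Per-item seeds derive deterministically from the master seed, so two runs
    with the same arguments produce identical files.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    rows = []
    for s in child_seeds:
        frame, mask, record = generate_phantom(params, int(s))
        img_path = out_dir / "images" / f"{frame.id}.png"
        msk_path = out_dir / "masks" / f"{mask.id}.png"
        write_frame(frame, img_path)
        write_mask(mask, msk_path)
        rows.append({
            "id": frame.id,
            "image_path": str(Path("images") / img_path.name),
            "mask_path": str(Path("masks") / msk_path.name),
            "row_mm_per_px": params.spacing_mm[0],
            "col_mm_per_px": params.spacing_mm[1],
        })
    return write_manifest(rows, out_dir / "manifest.csv")
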