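"""Pixel-overlap and boundary segmentation metrics.

Overlap scores are the five standard confusion-matrix ratios

    IoU = TP/(TP+FP+FN)        DSC = 2TP/(2TP+FP+FN)
    Rec = TP/(TP+FN)           Spe = TN/(TN+FP)        Pre = TP/(TP+FP)

computed per image and averaged with standard deviation across subjects.
HD95 is the 95th percentile of the pooled bidirectional boundary-to-boundary
surface distances (the dominant medical-imaging convention), in millimetres
under anisotropic pixel spacing.

Degenerate ratios (zero denominator) return 1.0 when the numerator condition
is vacuously perfect — e.g. recall with no positives in the reference and
none predicted — and 0.0 otherwise.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import ValidationError

__all__ = [
    "ConfusionCounts",
    "OverlapScores",
    "confusion_counts",
    "overlap_scores",
    "hd95",
    "evaluate_pairs",
    "write_evaluation_report",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclasses.dataclass(frozen=True)
class OverlapScores:
    iou: float
    dsc: float
    rec: float
    spe: float
    pre: float


def confusion_counts(pred, gt) -> ConfusionCounts:
    p = np.asarray(pred.labels if hasattr(pred, "labels") else pred).astype(bool)
    g = np.asarray(gt.labels if hasattr(gt, "labels") else gt).astype(bool)
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    tp = int(np.sum(p & g))
    fp = int(np.sum(p & ~g))
    tn = int(np.sum(~p & ~g))
    fn = int(np.sum(~p & g))
    return ConfusionCounts(tp, fp, tn, fn)


def _ratio(num: int, den: int, vacuous_perfect: bool) -> float:
    if den == 0:
        return 1.0 if vacuous_perfect else 0.0
    return num / den


def overlap_scores(c: ConfusionCounts) -> OverlapScores:
    # vacuous cases: no foreground anywhere (IoU/DSC/Pre), no gt positives
    # (Rec), no gt negatives (Spe) — perfect iff nothing was mispredicted
    return OverlapScores(
        iou=_ratio(c.tp, c.tp + c.fp + c.fn, vacuous_perfect=True),
        dsc=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, vacuous_perfect=True),
        rec=_ratio(c.tp, c.tp + c.fn, vacuous_perfect=c.fp == 0),
        spe=_ratio(c.tn, c.tn + c.fp, vacuous_perfect=c.fn == 0),
        pre=_ratio(c.tp, c.tp + c.fp, vacuous_perfect=c.fn == 0),
    )


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels: foreground minus its 8-connected erosion."""
    struct = np.ones((3, 3), dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def hd95(pred, gt, spacing_mm: tuple[float, float]) -> float:
    """95th percentile of pooled bidirectional surface distances, in mm."""
    p = np.asarray(pred.labels if hasattr(pred, "labels") else pred).astype(bool)
    g = np.asarray(gt.labels if hasattr(gt, "labels") else gt).astype(bool)
    if p.shape != g.shape:
        raise ValidationError(f"shape mismatch: pred {p.shape} vs gt {g.shape}")
    if not p.any() or not g.any():
        raise ValidationError("HD95 undefined: empty mask has no boundary")
    bp, bg = _boundary(p), _boundary(g)
    # distance-to-boundary fields under anisotropic spacing
    dist_to_g = ndimage.distance_transform_edt(~bg, sampling=spacing_mm)
    dist_to_p = ndimage.distance_transform_edt(~bp, sampling=spacing_mm)
    pooled = np.concatenate([dist_to_g[bp], dist_to_p[bg]])
    return float(np.percentile(pooled, 95))


def evaluate_pairs(pred_masks, gt_masks, spacing_mm: tuple[float, float]) -> pd.DataFrame:
    """Per-image metric rows for paired prediction/reference masks."""
    rows = []
    for pm, gm in zip(pred_masks, gt_masks):
        s = overlap_scores(confusion_counts(pm, gm))
        row = {"id": getattr(gm, "id", ""), "pre": s.pre, "iou": s.iou,
               "rec": s.rec, "spe": s.spe, "dsc": s.dsc}
        try:
            row["hd95_mm"] = hd95(pm, gm, spacing_mm)
        except ValidationError:
            row["hd95_mm"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_evaluation_report(df: pd.DataFrame, path) -> Path:
    """One row per image plus a mean +- sd summary row (Pre, IoU, Rec, DSC,
    HD95 column order)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = ["id", "pre", "iou", "rec", "spe", "dsc", "hd95_mm"]
    out = df[cols].copy()
    num = out.drop(columns=["id"])
    summary = {"id": "mean±sd"}
    for c in num.columns:
        summary[c] = f"{num[c].mean():.4f}±{num[c].std(ddof=1):.4f}"
    out = pd.concat([out, pd.DataFrame([summary])], ignore_index=True)
    out.to_csv(path, index=False)
    return path
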