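"""Eye-muscle-area measurement and agreement analysis.

The automated phenotype is obtained in two steps: count foreground pixels in
the predicted binary mask, then convert to physical area with the device
calibration (mm per pixel along each axis, so one pixel covers
``row_mm * col_mm`` mm²).  Agreement between automated and reference areas is
summarized by four complementary statistics:

* MAE   — mean absolute error, ``mean(|Yhat - Y|)``;
* MAPE  — mean absolute percentage error, ``mean(|Yhat - Y| / Y) * 100``;
* SEM   — signed error mean ``mean(Yhat - Y)``, the systematic bias
          (positive = overestimation);
* r     — Pearson correlation between the two series.

Errors can be expressed in pixels or mm²; the report tags the unit so the two
are never silently mixed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ValidationError

__all__ = [
    "Calibration",
    "AreaRecord",
    "AgreementReport",
    "measure_area",
    "agreement_stats",
    "improvement_stats",
    "write_agreement_report",
]


@dataclasses.dataclass(frozen=True)
class Calibration:
    """Physical size of one pixel (mm per pixel per axis)."""

    row_mm_per_px: float
    col_mm_per_px: float

    def __post_init__(self):
        if self.row_mm_per_px <= 0 or self.col_mm_per_px <= 0:
            raise ValidationError("calibration components must be positive")

    @property
    def area_per_pixel_mm2(self) -> float:
        return self.row_mm_per_px * self.col_mm_per_px


@dataclasses.dataclass(frozen=True)
class AreaRecord:
    """One animal's pixel count and calibrated physical area."""

    id: str
    pixel_count: int
    area_mm2: float


@dataclasses.dataclass
class AgreementReport:
    n: int
    unit: str                   # "px" or "mm2"
    mae: float
    mape_pct: float
    sem: float
    r: float
    r_degenerate: bool          # True when both series were identical
    mean_auto: float
    sd_auto: float
    min_auto: float
    max_auto: float
    mean_ref: float
    sd_ref: float
    min_ref: float
    max_ref: float
    mean_bias: float            # mean(auto) - mean(ref) == SEM

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def measure_area(mask, cal: Calibration) -> AreaRecord:
    """Foreground pixel count converted to physical area."""
    count = int(np.asarray(mask.labels).sum())
    return AreaRecord(id=mask.id, pixel_count=count,
                      area_mm2=count * cal.area_per_pixel_mm2)


def agreement_stats(reference, automated, unit: str = "mm2") -> AgreementReport:
    """Agreement statistics between reference (Y) and automated (Yhat) areas."""
    y = np.asarray(reference, dtype=np.float64)
    yhat = np.asarray(automated, dtype=np.float64)
    if y.shape != yhat.shape or y.ndim != 1:
        raise ValidationError("reference and automated must be equal-length 1-D lists")
    n = y.size
    if n < 2:
        raise ValidationError("agreement statistics require n >= 2")
    if unit not in ("px", "mm2"):
        raise ValidationError(f"unknown unit {unit!r}")
    if np.any(y == 0):
        raise ValidationError("MAPE undefined: reference contains zero values")

    err = yhat - y
    mae = float(np.mean(np.abs(err)))
    mape = float(np.mean(np.abs(err) / np.abs(y)) * 100.0)
    sem = float(np.mean(err))

    degenerate = False
    if np.allclose(y, yhat):
        # identical series: r is 0/0; report perfect agreement with a flag
        r_val, degenerate = 1.0, True
    else:
        if np.ptp(y) == 0 or np.ptp(yhat) == 0:
            raise ValidationError("correlation undefined for a constant series")
        yc, hc = y - y.mean(), yhat - yhat.mean()
        r_val = float((yc * hc).sum() / np.sqrt((yc * yc).sum() * (hc * hc).sum()))

    return AgreementReport(
        n=n, unit=unit, mae=mae, mape_pct=mape, sem=sem,
        r=r_val, r_degenerate=degenerate,
        mean_auto=float(yhat.mean()), sd_auto=float(yhat.std(ddof=1)),
        min_auto=float(yhat.min()), max_auto=float(yhat.max()),
        mean_ref=float(y.mean()), sd_ref=float(y.std(ddof=1)),
        min_ref=float(y.min()), max_ref=float(y.max()),
        mean_bias=float(yhat.mean() - y.mean()),
    )


def improvement_stats(metric_a: float, metric_b: float) -> tuple[float, float]:
    """Absolute (b - a) and relative 100*(b - a)/a change, e.g. between two
    models' IoU percentages.  Relative change is rounded to 2 decimals for
    reporting."""
    if np.isnan(metric_a) or np.isnan(metric_b):
        raise ValidationError("improvement inputs must be finite")
    absolute = metric_b - metric_a
    if metric_a <= 0:
        raise ValidationError("relative improvement requires a positive baseline")
    relative = round(100.0 * absolute / metric_a, 2)
    return absolute, relative


def write_agreement_report(report: AgreementReport, out_dir,
                           pairs: pd.DataFrame | None = None,
                           plot: bool = False) -> dict:
    """Serialize a report as JSON + CSV (descriptive-statistics layout:
    per-method Mean +- SD / Min / Max plus a Difference (Bias) row).
    Optionally writes a scatter plot of automated vs reference areas."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    json_path = out_dir / "agreement.json"
    json_path.write_text(json.dumps(report.to_dict(), indent=2))
    paths["json"] = json_path

    rows = [
        {"measurement_method": "Reference (Ground Truth)",
         "mean": report.mean_ref, "sd": report.sd_ref,
         "min": report.min_ref, "max": report.max_ref},
        {"measurement_method": "Automated Method",
         "mean": report.mean_auto, "sd": report.sd_auto,
         "min": report.min_auto, "max": report.max_auto},
        {"measurement_method": "Difference (Bias)",
         "mean": report.mean_bias,
         "sd": float(np.nan), "min": float(np.nan), "max": float(np.nan)},
    ]
    csv_path = out_dir / "agreement_descriptive.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    paths["csv"] = csv_path

    if pairs is not None:
        pairs_path = out_dir / "area_pairs.csv"
        pairs.to_csv(pairs_path, index=False)
        paths["pairs"] = pairs_path

    if plot and pairs is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(pairs["reference"], pairs["automated"], s=18, alpha=0.8)
        lims = [min(pairs.min().min(), 0), pairs.max().max() * 1.05]
        ax.plot(lims, lims, "k--", lw=1)
        ax.set_xlabel(f"reference area ({report.unit})")
        ax.set_ylabel(f"automated area ({report.unit})")
        ax.set_title(f"n={report.n}  MAE={report.mae:.2f} {report.unit}  r={report.r:.4f}")
        plot_path = out_dir / "agreement_scatter.png"
        fig.savefig(plot_path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths["plot"] = plot_path
    return paths
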