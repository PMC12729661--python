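"""emaseg: ultrasound eye-muscle segmentation and automated area measurement.

A state-space (Mamba-style) U-shaped segmentation network with edge-enhanced
skip connections, a pyramid-attention bottleneck and a context-aggregation
decoder, plus the measurement pipeline that turns predicted masks into
calibrated physical areas and agreement statistics.  Runs on a small numpy
autodiff engine (:mod:`emaseg.nn`); synthetic speckle phantoms
(:mod:`emaseg.phantom`) provide ground-truthed test data.
"""

__version__ = "0.1.0"


class EmasegError(Exception):
    """Base class for package errors."""


class ValidationError(EmasegError):
    """Invalid inputs, shapes, or configuration (CLI exit code 2)."""


class IOErrorEmaseg(EmasegError):
    """File read/write failures (CLI exit code 3)."""


from . import nn  # noqa: E402
from .configs import AugmentPolicy, RunConfig, full_size, test_profile  # noqa: E402
from .data import (  # noqa: E402
    BinaryMask,
    SplitSpec,
    UltrasoundFrame,
    load_frame,
    load_mask,
    preprocess,
    read_manifest,
    split_dataset,
    write_mask,
)
from .ema import (  # noqa: E402
    AgreementReport,
    AreaRecord,
    Calibration,
    agreement_stats,
    improvement_stats,
    measure_area,
)
from .metrics import (  # noqa: E402
    ConfusionCounts,
    OverlapScores,
    confusion_counts,
    hd95,
    overlap_scores,
)
from .phantom import PhantomParams, generate_dataset, generate_phantom  # noqa: E402

__all__ = [
    "__version__",
    "EmasegError", "ValidationError", "IOErrorEmaseg",
    "nn",
    "AugmentPolicy", "RunConfig", "full_size", "test_profile",
    "UltrasoundFrame", "BinaryMask", "SplitSpec",
    "load_frame", "load_mask", "write_mask", "preprocess", "split_dataset",
    "read_manifest",
    "Calibration", "AreaRecord", "AgreementReport",
    "measure_area", "agreement_stats", "improvement_stats",
    "ConfusionCounts", "OverlapScores", "confusion_counts", "overlap_scores",
    "hd95",
    "PhantomParams", "generate_phantom", "generate_dataset",
]
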