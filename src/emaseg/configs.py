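"""Run configuration (training hyper-parameters, model widths, augmentation
policy) with YAML round-tripping and two named profiles:

* ``full_size``  — the deployment configuration: 512x512 inputs, base width
  48 (channel ladder 48..768), 2 VSS blocks per stage, AdamW at 1e-4 with
  weight decay 5e-2, batch 12, 50 epochs.
* ``test_profile`` — a reduced configuration for CPU-scale suites and
  overfit experiments: 128x128 inputs, base width 16, one VSS block per
  stage, smaller pooling pyramid (the 4x4 bottleneck cannot host a 7x7
  pooling grid), higher learning rate suited to tiny-sample overfitting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from . import ValidationError

__all__ = ["AugmentPolicy", "RunConfig", "full_size", "test_profile",
           "load_config", "save_config"]


@dataclasses.dataclass
class AugmentPolicy:
    """Per-transform probabilities and ranges (training only)."""

    rotation_prob: float = 0.2
    rotation_deg: float = 30.0
    scale_prob: float = 0.2
    scale_range: tuple[float, float] = (0.7, 1.4)
    elastic_prob: float = 0.2
    elastic_alpha: float = 10.0      # displacement amplitude, px
    elastic_sigma: float = 8.0       # displacement field smoothness, px
    brightness_prob: float = 0.15
    brightness_range: tuple[float, float] = (0.75, 1.25)
    contrast_prob: float = 0.15
    contrast_range: tuple[float, float] = (0.75, 1.25)
    noise_prob: float = 0.1
    noise_sigma_max: float = 0.1

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if f.name.endswith("_prob"):
                v = getattr(self, f.name)
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{f.name}={v} outside [0, 1]")

    @classmethod
    def disabled(cls) -> "AugmentPolicy":
        return cls(rotation_prob=0, scale_prob=0, elastic_prob=0,
                   brightness_prob=0, contrast_prob=0, noise_prob=0)


@dataclasses.dataclass
class RunConfig:
    epochs: int = 50
    batch_size: int = 12
    learning_rate: float = 1e-4
    weight_decay: float = 5e-2
    optimizer: str = "adamw"
    input_size: int = 512
    base_channels: int = 48
    stage_depths: tuple[int, ...] = (2, 2, 2, 2)
    d_state: int = 16
    expand: int = 2
    pool_sizes: tuple[int, ...] = (1, 3, 5, 7)
    threshold: float = 0.5
    seed: int = 0
    augment: AugmentPolicy = dataclasses.field(default_factory=AugmentPolicy)

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValidationError("epochs and batch_size must be positive")
        if self.input_size % 32:
            raise ValidationError(f"input_size {self.input_size} must be divisible by 32")
        if self.optimizer.lower() != "adamw":
            raise ValidationError(f"unsupported optimizer {self.optimizer!r}")
        self.stage_depths = tuple(self.stage_depths)
        self.pool_sizes = tuple(self.pool_sizes)
        if isinstance(self.augment, dict):
            self.augment = AugmentPolicy(**self.augment)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_depths"] = list(self.stage_depths)
        d["pool_sizes"] = list(self.pool_sizes)
        return d


def full_size(**overrides) -> RunConfig:
    return RunConfig(**overrides)


def test_profile(**overrides) -> RunConfig:
    defaults = dict(epochs=40, batch_size=4, learning_rate=1e-3,
                    input_size=128, base_channels=16, stage_depths=(1, 1, 1, 1),
                    pool_sizes=(1, 3))
    defaults.update(overrides)
    return RunConfig(**defaults)


def save_config(config: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} is not a mapping")
    aug = raw.pop("augment", None)
    cfg = RunConfig(**raw)
    if aug is not None:
        scale = aug.get("scale_range")
        bright = aug.get("brightness_range")
        contrast = aug.get("contrast_range")
        for key, val in (("scale_range", scale), ("brightness_range", bright),
                         ("contrast_range", contrast)):
            if val is not None:
                aug[key] = tuple(val)
        cfg.augment = AugmentPolicy(**aug)
    return cfg
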