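"""Full network assembly: state-space encoder, edge-enhanced skips, pyramid
attention bottleneck, and the context-aggregation decoder.

Grayscale frames are replicated to 3 channels before the stem so externally
trained 3-channel backbone weights remain shape-compatible (loading such
weights is optional and off by default)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import ValidationError
from .backbone import Encoder, FeaturePyramid
from .configs import RunConfig
from .gcad import Decoder
from .msee import MSEE
from .nn import autograd as ag
from .nn.autograd import Tensor, no_grad
from .nn.modules import Module, ModuleList
from .parm import PARM

__all__ = ["MPGSwinUMamba", "build_model", "save_checkpoint", "load_checkpoint"]


class MPGSwinUMamba(Module):
    def __init__(self, base_channels: int = 48, stage_depths=(2, 2, 2, 2),
                 d_state: int = 16, expand: int = 2, pool_sizes=(1, 3, 5, 7),
                 use_gcad: bool = True, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(seed)
        b = base_channels
        self.encoder = Encoder(b, stage_depths, d_state=d_state, expand=expand, rng=rng)
        # edge-enhanced skips at the four levels the decoder consumes
        self.msees = ModuleList([MSEE(c, rng=rng) for c in (b, 2 * b, 4 * b, 8 * b)])
        self.parm = PARM(16 * b, pool_sizes=pool_sizes, rng=rng)
        self.decoder = Decoder(b, use_gcad=use_gcad, rng=rng)
        self.base_channels = b

    def encode(self, x: Tensor) -> FeaturePyramid:
        if x.shape[1] == 1:
            x = ag.concat([x, x, x], axis=1)
        elif x.shape[1] != 3:
            raise ValidationError(f"expected 1 or 3 input channels, got {x.shape[1]}")
        return self.encoder(x)

    def forward(self, x: Tensor) -> Tensor:
        """x: (B, 1|3, S, S) in [0,1] -> logits (B, 1, S, S)."""
        pyramid = self.encode(x)
        bottleneck = self.parm(pyramid.levels[4])
        skips = [self.msees[i](pyramid.levels[i]) for i in (3, 2, 1, 0)]
        return self.decoder(pyramid, bottleneck, skips=skips)

    def predict_proba(self, x: Tensor) -> np.ndarray:
        self.eval()
        with no_grad():
            logits = self.forward(x)
            probs = ag.sigmoid(logits)
        return probs.data


def build_model(config: RunConfig, use_gcad: bool = True) -> MPGSwinUMamba:
    return MPGSwinUMamba(base_channels=config.base_channels,
                         stage_depths=config.stage_depths,
                         d_state=config.d_state, expand=config.expand,
                         pool_sizes=config.pool_sizes,
                         use_gcad=use_gcad, seed=config.seed)


def save_checkpoint(model: MPGSwinUMamba, config: RunConfig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = model.state_dict()
    np.savez(path, **state)  # uncompressed: checkpoints are scratch artifacts
    Path(str(path) + ".config.json").write_text(json.dumps(config.to_dict(), indent=2))
    return path


def load_checkpoint(path, config: RunConfig | None = None) -> tuple[MPGSwinUMamba, RunConfig]:
    path = Path(path)
    cfg_path = Path(str(path) + ".config.json")
    if config is None:
        if not cfg_path.exists():
            raise ValidationError(f"no config found beside checkpoint {path}")
        raw = json.loads(cfg_path.read_text())
        raw.pop("augment", None)
        config = RunConfig(**raw)
    model = build_model(config)
    with np.load(path) as npz:
        state = {k: npz[k] for k in npz.files}
    model.load_state_dict(state)
    return model, config
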