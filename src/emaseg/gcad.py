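"""Global Context Aggregation Decoder.

Each decoder stage upsamples 2x with channel halving (a 2x2 stride-2
transposed convolution, realized exactly as a 1x1 convolution to 4x the
target width followed by depth-to-space), concatenates the edge-enhanced
skip, fuses with a 1x1 convolution to the stage width, and refines with a
GCAD block:

    XA  = Norm(X)
    XS1 = XA + Norm(MCA(XA))
    Y   = XS1 + MLP(XS1)

The MCA sub-layer aggregates context hierarchically with three dilated
depthwise-separable 3x3 convolutions (rates 6 -> 4 -> 2, each fed the input
plus the previous branch), an average-pooling branch (3x3, stride 1 — a
global pool would not be shape-compatible with the F1+F4 addition), a 4C-wide
concatenation, and a multiplicative SiLU gate with two independently
parameterized 1x1 paths.  A final expansion from S/2 to S and a 1x1
convolution produce the single-channel logits map.
"""

from __future__ import annotations

from . import ValidationError
from .backbone import FeaturePyramid
from .nn import autograd as ag
from .nn import functional as F
from .nn.autograd import Tensor
from .nn.modules import (
    ChannelLayerNorm,
    Conv2d,
    DepthwiseSeparableConv2d,
    Identity,
    Module,
    ModuleList,
)

__all__ = ["MCA", "GCADBlock", "Upsample2x", "Decoder"]


class MCA(Module):
    """Hierarchical dilated multi-scale context aggregation with gating."""

    def __init__(self, channels: int, rng=None):
        super().__init__()
        C = channels
        self.dwc6 = DepthwiseSeparableConv2d(C, C, 3, dilation=6, rng=rng)
        self.dwc4 = DepthwiseSeparableConv2d(C, C, 3, dilation=4, rng=rng)
        self.dwc2 = DepthwiseSeparableConv2d(C, C, 3, dilation=2, rng=rng)
        self.gate_a = Conv2d(4 * C, C, 1, rng=rng)
        self.gate_b = Conv2d(4 * C, C, 1, rng=rng)
        self.fuse = Conv2d(C, C, 1, rng=rng)

    def forward(self, xa: Tensor) -> Tensor:
        f1 = self.dwc6(xa)
        f2 = self.dwc4(xa + f1)
        f3 = self.dwc2(xa + f2)
        f4 = F.avg_pool2d_3x3(xa)
        xcon = ag.concat([xa, f2, f3, f1 + f4], axis=1)     # width 4C
        return self.fuse(F.silu(self.gate_a(xcon)) * F.silu(self.gate_b(xcon)))


class GCADBlock(Module):
    """Pre-norm residual wrapper around MCA plus a pointwise MLP."""

    def __init__(self, channels: int, mlp_ratio: int = 4, rng=None):
        super().__init__()
        self.norm1 = ChannelLayerNorm(channels)
        self.norm2 = ChannelLayerNorm(channels)
        self.mca = MCA(channels, rng=rng)
        self.mlp_fc1 = Conv2d(channels, mlp_ratio * channels, 1, rng=rng)
        self.mlp_fc2 = Conv2d(mlp_ratio * channels, channels, 1, rng=rng)

    def mlp(self, x: Tensor) -> Tensor:
        return self.mlp_fc2(ag.gelu(self.mlp_fc1(x)))

    def forward(self, x: Tensor) -> Tensor:
        xa = self.norm1(x)
        xs1 = xa + self.norm2(self.mca(xa))
        return xs1 + self.mlp(xs1)


class Upsample2x(Module):
    """2x2 stride-2 transposed convolution as 1x1 conv + depth-to-space."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, 4 * out_ch, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return F.depth_to_space(self.conv(x), 2)


class Decoder(Module):
    """Upsampling/fusion ladder from the refined bottleneck to full-res logits.

    ``use_gcad=False`` replaces every GCAD block with identity (ablation
    hook); the ladder still type-checks and runs.
    """

    def __init__(self, base_channels: int = 48, use_gcad: bool = True, rng=None):
        super().__init__()
        b = base_channels
        widths = [8 * b, 4 * b, 2 * b, b]           # e.g. 384, 192, 96, 48
        self.ups = ModuleList([Upsample2x(2 * w, w, rng=rng) for w in widths])
        self.fusions = ModuleList([Conv2d(2 * w, w, 1, rng=rng) for w in widths])
        self.blocks = ModuleList([GCADBlock(w, rng=rng) if use_gcad else Identity()
                                  for w in widths])
        self.final_up = Upsample2x(b, b // 2, rng=rng)
        self.head = Conv2d(b // 2, 1, 1, rng=rng)
        self.widths = widths

    def forward(self, pyramid: FeaturePyramid, bottleneck: Tensor,
                skips: list[Tensor] | None = None) -> Tensor:
        """``skips`` are the edge-enhanced levels (deep to shallow, matching
        ``widths``); defaults to the raw pyramid levels 3..0."""
        if bottleneck.shape[1] != 2 * self.widths[0]:
            raise ValidationError(
                f"bottleneck width {bottleneck.shape[1]} != {2 * self.widths[0]}")
        if skips is None:
            skips = [pyramid.levels[i] for i in (3, 2, 1, 0)]
        h = bottleneck
        for up, fuse, block, skip, w in zip(self.ups, self.fusions, self.blocks,
                                            skips, self.widths):
            h = up(h)
            if h.shape[2:] != skip.shape[2:] or skip.shape[1] != w:
                raise ValidationError(
                    f"skip {skip.shape} incompatible with decoder stage width {w}")
            h = fuse(ag.concat([h, skip], axis=1))
            h = block(h)
        return self.head(self.final_up(h))
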