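"""Five-stage state-space encoder.

Stage 0 is a convolutional stem (7x7, stride 2, instance norm).  Stage 1
embeds non-overlapping 2x2 patches; stages 2-4 merge 2x2 neighbourhoods and
double the channel count.  Each post-stem stage runs a series of VSS blocks
whose sequence core is the SS2D four-directional selective scan: the feature
map is flattened row-major and column-major, each forward and backward, every
traversal runs an input-dependent state-space recurrence, and the four
outputs are merged.  With base width 48 the pyramid channels are
48 -> 96 -> 192 -> 384 -> 768 at strides /2 ... /32, and no positional
embeddings are used anywhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import ValidationError
from .nn import autograd as ag
from .nn import functional as F
from .nn.autograd import Tensor
from .nn.modules import (
    ChannelLayerNorm,
    Conv2d,
    InstanceNorm2d,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Parameter,
)
from .nn.scan import selective_scan

__all__ = ["FeaturePyramid", "Stem", "PatchEmbed", "PatchMerging", "SS2D",
           "VSSBlock", "Encoder"]


@dataclasses.dataclass
class FeaturePyramid:
    """Ordered per-stage feature maps (B, C, H, W), strides /2 ... /32."""

    levels: list

    def __post_init__(self):
        if len(self.levels) != 5:
            raise ValidationError("feature pyramid must have 5 levels")
        c0 = self.levels[0].shape[1]
        for i, lv in enumerate(self.levels):
            if lv.shape[1] != c0 * (2 ** i):
                raise ValidationError(
                    f"level {i}: channels {lv.shape[1]} != {c0 * 2 ** i}")
            if i > 0:
                prev = self.levels[i - 1]
                if (prev.shape[2] != lv.shape[2] * 2) or (prev.shape[3] != lv.shape[3] * 2):
                    raise ValidationError(f"level {i} does not halve level {i - 1}")

    @property
    def channels(self):
        return [lv.shape[1] for lv in self.levels]


class Stem(Module):
    """7x7 stride-2 convolution + 2-D instance normalization."""

    def __init__(self, out_ch: int = 48, in_ch: int = 3, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 7, stride=2, padding=3, rng=rng)
        self.norm = InstanceNorm2d(out_ch)
        self.in_ch = in_ch

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_ch:
            raise ValidationError(f"stem expects {self.in_ch} channels, got {x.shape[1]}")
        return self.norm(self.conv(x))


class PatchEmbed(Module):
    """Non-overlapping 2x2 convolutional embedding (randomly initialized)."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, out_ch, 2, stride=2, rng=rng)
        self.norm = ChannelLayerNorm(out_ch)

    def forward(self, x):
        return self.norm(self.conv(x))


class PatchMerging(Module):
    """2x2 neighbourhood concatenation + linear reduction to double width."""

    def __init__(self, in_ch: int, rng=None):
        super().__init__()
        self.norm = LayerNorm(4 * in_ch)
        self.reduction = Linear(4 * in_ch, 2 * in_ch, bias=False, rng=rng)

    def forward(self, x):
        q = ag.concat([x[:, :, 0::2, 0::2], x[:, :, 1::2, 0::2],
                       x[:, :, 0::2, 1::2], x[:, :, 1::2, 1::2]], axis=1)
        q = ag.transpose(q, (0, 2, 3, 1))          # channels last for the linear
        q = self.reduction(self.norm(q))
        return ag.transpose(q, (0, 3, 1, 2))


def _softplus_inverse(x: np.ndarray) -> np.ndarray:
    return x + np.log(-np.expm1(-x))


class SS2D(Module):
    """Four-directional selective 2-D scan.

    Each direction owns its input projection (giving per-step Delta, B, C),
    step-size projection, decay matrix A (= -exp(A_log), always stable) and
    skip coefficient D.  Outputs of the four traversals are summed and layer
    normalized.
    """

    DIRECTIONS = 4

    def __init__(self, channels: int, d_state: int = 16, dt_rank: int | None = None,
                 rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.channels, self.d_state = channels, d_state
        self.dt_rank = dt_rank if dt_rank is not None else max(1, channels // 16)
        if d_state < 1:
            raise ValidationError("state dimension must be >= 1")

        self.x_proj = ModuleList(
            [Linear(channels, self.dt_rank + 2 * d_state, bias=False, rng=rng)
             for _ in range(self.DIRECTIONS)])
        dt_projs = []
        for _ in range(self.DIRECTIONS):
            lin = Linear(self.dt_rank, channels, bias=True, rng=rng)
            # initialize bias so softplus(bias) is log-uniform in [1e-3, 1e-1]
            dt = np.exp(rng.uniform(np.log(1e-3), np.log(1e-1), size=channels))
            lin.bias.data = _softplus_inverse(dt).astype(lin.bias.dtype)
            dt_projs.append(lin)
        self.dt_proj = ModuleList(dt_projs)
        a_init = np.log(np.arange(1, d_state + 1, dtype=np.float32))
        self.A_log = [Parameter(np.tile(a_init, (channels, 1)))
                      for _ in range(self.DIRECTIONS)]
        self.D = [Parameter(np.ones(channels, dtype=np.float32))
                  for _ in range(self.DIRECTIONS)]
        self.out_norm = LayerNorm(channels)

    def _scan_direction(self, seq: Tensor, k: int) -> Tensor:
        """seq: (B, C, L) in traversal order for direction k."""
        b, c, L = seq.shape
        cl = ag.transpose(seq, (0, 2, 1))                    # (B, L, C)
        proj = self.x_proj[k](cl)                            # (B, L, R + 2N)
        R, N = self.dt_rank, self.d_state
        dt = ag.softplus(self.dt_proj[k](proj[:, :, :R]))    # (B, L, C), > 0
        Bmat = ag.transpose(proj[:, :, R:R + N], (0, 2, 1))  # (B, N, L)
        Cmat = ag.transpose(proj[:, :, R + N:], (0, 2, 1))   # (B, N, L)
        A = -ag.exp(self.A_log[k])                           # (C, N), < 0
        return selective_scan(seq, ag.transpose(dt, (0, 2, 1)), A, Bmat, Cmat,
                              self.D[k])

    def forward(self, x: Tensor) -> Tensor:
        if not np.isfinite(x.data).all():
            raise ValidationError("SS2D input contains non-finite values")
        B, C, H, W = x.shape
        L = H * W
        row = ag.reshape(x, (B, C, L))                                   # row-major
        col = ag.reshape(ag.transpose(x, (0, 1, 3, 2)), (B, C, L))       # column-major

        y0 = self._scan_direction(row, 0)
        y1 = self._scan_direction(col, 1)
        y2 = ag.flip(self._scan_direction(ag.flip(row, 2), 2), 2)
        y3 = ag.flip(self._scan_direction(ag.flip(col, 2), 3), 2)

        y_row = y0 + y2
        y_col = ag.transpose(ag.reshape(y1 + y3, (B, C, W, H)), (0, 1, 3, 2))
        y = ag.reshape(y_row, (B, C, H, W)) + y_col
        y = ag.transpose(y, (0, 2, 3, 1))
        y = self.out_norm(y)
        return ag.transpose(y, (0, 3, 1, 2))


class VSSBlock(Module):
    """Two-branch gated unit around the SS2D core, with a residual.

    out = x + Linear( act(Linear(LN x)) * LN(SS2D(act(DWConv(Linear(LN x))))) )
    """

    def __init__(self, channels: int, d_state: int = 16, expand: int = 2, rng=None):
        super().__init__()
        inner = expand * channels
        self.norm = LayerNorm(channels)
        self.in_proj = Linear(channels, 2 * inner, rng=rng)
        self.dwconv = Conv2d(inner, inner, 3, padding=1, groups=inner, bias=True, rng=rng)
        self.ss2d = SS2D(inner, d_state=d_state, rng=rng)
        self.out_proj = Linear(inner, channels, rng=rng)
        self.inner = inner

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        xl = ag.transpose(x, (0, 2, 3, 1))
        xn = self.norm(xl)
        both = self.in_proj(xn)                      # (B, H, W, 2*inner)
        gate = F.silu(both[:, :, :, :self.inner])
        z = both[:, :, :, self.inner:]
        z = ag.transpose(z, (0, 3, 1, 2))
        z = F.silu(self.dwconv(z))
        y = self.ss2d(z)                             # includes its own LN
        y = ag.transpose(y, (0, 2, 3, 1))
        out = self.out_proj(y * gate)
        return x + ag.transpose(out, (0, 3, 1, 2))


class Encoder(Module):
    """Stem + patch embedding/merging + VSS stages -> 5-level pyramid."""

    def __init__(self, base_channels: int = 48, stage_depths=(2, 2, 2, 2),
                 d_state: int = 16, expand: int = 2, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if len(stage_depths) != 4:
            raise ValidationError("stage_depths must list 4 VSS stages")
        b = base_channels
        self.stem = Stem(b, rng=rng)
        self.patch_embed = PatchEmbed(b, 2 * b, rng=rng)
        self.mergings = ModuleList([PatchMerging(2 * b * 2 ** i, rng=rng)
                                    for i in range(3)])
        self.stages = ModuleList([
            ModuleList([VSSBlock(2 * b * 2 ** i, d_state=d_state, expand=expand, rng=rng)
                        for _ in range(depth)])
            for i, depth in enumerate(stage_depths)])
        self.base_channels = b

    def forward(self, x: Tensor) -> FeaturePyramid:
        B, C, H, W = x.shape
        if H % 32 or W % 32:
            raise ValidationError(f"input size {H}x{W} must be divisible by 32")
        levels = [self.stem(x)]
        h = self.patch_embed(levels[0])
        for blk in self.stages[0]:
            h = blk(h)
        levels.append(h)
        for i in range(3):
            h = self.mergings[i](h)
            for blk in self.stages[i + 1]:
                h = blk(h)
            levels.append(h)
        return FeaturePyramid(levels=levels)
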