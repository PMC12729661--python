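"""Pyramid Attention Refinement Module (bottleneck).

Stage one pools the bottleneck map onto several coarse grids (1x1 ... 7x7 by
default), upsamples each back bilinearly and concatenates with the input,
forming a compact context pyramid.  Stage two compresses channels and runs
non-local attention over all spatial position pairs: query and key come from
the pooled pyramid, the value embedding from the raw input, similarities are
softmax-normalized per query position, and the attention runs independently
on channel groups for efficiency.  A final 1x1 convolution restores the
original width and the input is added residually, so zeroing that convolution
makes the module an exact identity.
"""

from __future__ import annotations

from . import ValidationError
from .nn import autograd as ag
from .nn import functional as F
from .nn.autograd import Tensor
from .nn.modules import Conv2d, Module

__all__ = ["PARM"]


class PARM(Module):
    def __init__(self, channels: int, pool_sizes=(1, 3, 5, 7),
                 compress_ratio: int = 4, groups: int = 4, rng=None):
        super().__init__()
        C = channels
        Cp = max(groups, C // compress_ratio)
        if Cp >= C:
            raise ValidationError("compressed width must be smaller than C")
        if Cp % groups:
            raise ValidationError(f"compressed width {Cp} not divisible by {groups} groups")
        self.pool_sizes = tuple(pool_sizes)
        k = len(self.pool_sizes) + 1
        self.phi = Conv2d(k * C, Cp, 1, rng=rng)      # query
        self.theta = Conv2d(k * C, Cp, 1, rng=rng)    # key
        self.g = Conv2d(C, Cp, 1, rng=rng)            # value, from raw x
        self.out_conv = Conv2d(Cp, C, 1, rng=rng)
        self.groups = groups
        self.channels, self.compressed = C, Cp

    def pyramid_pool_concat(self, x: Tensor) -> Tensor:
        """Adaptive-average pool to each grid, upsample back, concat with x."""
        B, C, H, W = x.shape
        if self.pool_sizes and (H < max(self.pool_sizes) or W < max(self.pool_sizes)):
            raise ValidationError(
                f"spatial size {H}x{W} below largest pooling grid {max(self.pool_sizes)}")
        branches = [F.bilinear_resize(F.adaptive_avg_pool2d(x, (g, g)), (H, W))
                    for g in self.pool_sizes]
        return ag.concat(branches + [x], axis=1)

    def _grouped_attention(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        """q, k, v: (B, C', HW).  Per group: each query position's softmax
        weights over key positions aggregate the value embedding."""
        B, Cp, L = q.shape
        cg = Cp // self.groups
        outs = []
        for gi in range(self.groups):
            sl = slice(gi * cg, (gi + 1) * cg)
            logits = ag.matmul(ag.transpose(q[:, sl], (0, 2, 1)), k[:, sl])  # (B, Lq, Lk)
            w = F.softmax(logits, axis=-1)
            outs.append(ag.matmul(v[:, sl], ag.transpose(w, (0, 2, 1))))     # (B, cg, Lq)
        return ag.concat(outs, axis=1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        pm = self.pyramid_pool_concat(x)
        q = ag.reshape(self.phi(pm), (B, self.compressed, H * W))
        k = ag.reshape(self.theta(pm), (B, self.compressed, H * W))
        v = ag.reshape(self.g(x), (B, self.compressed, H * W))
        att = self._grouped_attention(q, k, v)
        att = ag.reshape(att, (B, self.compressed, H, W))
        return self.out_conv(att) + x
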