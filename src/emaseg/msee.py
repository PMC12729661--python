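"""Multi-Scale Edge-Enhanced skip-connection block.

Two parallel paths refine each encoder skip before the decoder consumes it:

* the *context path* gathers multi-scale context (a 1x1 convolution plus
  three 3x3 dilated convolutions at rates 6/12/18, summed and normalized)
  and runs transposed channel attention on it — Q/K/V are produced by
  pointwise-then-depthwise convolutions, the C x C attention map is
  softmax-normalized over its last axis with a learnable scalar temperature,
  and the attended value map is projected back by a 1x1 depthwise-separable
  convolution;
* the *edge path* applies a fixed Sobel operator depthwise (gradient
  magnitude, replicate padding so constants give exactly zero response),
  batch-norm + ReLU, a 3x3 depthwise-separable convolution, a residual
  addition of the input, and a final 1x1 projection.

The module output is the element-wise sum of the two paths.
"""

from __future__ import annotations

import numpy as np

from .nn import autograd as ag
from .nn import functional as F
from .nn.autograd import Tensor
from .nn.modules import (
    BatchNorm2d,
    ChannelLayerNorm,
    Conv2d,
    DepthwiseSeparableConv2d,
    Module,
    Parameter,
)

__all__ = ["sobel_magnitude", "MSEE"]

_SOBEL_GX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=np.float32)
_SOBEL_GY = _SOBEL_GX.T.copy()


def sobel_magnitude(x: Tensor, eps: float = 1e-12) -> Tensor:
    """Depthwise Sobel gradient magnitude sqrt(Gx^2 + Gy^2 + eps).

    Replicate padding makes the response exactly zero on spatially constant
    inputs, borders included.
    """
    C = x.shape[1]
    wx = Tensor(np.broadcast_to(_SOBEL_GX, (C, 1, 3, 3)).astype(x.dtype).copy())
    wy = Tensor(np.broadcast_to(_SOBEL_GY, (C, 1, 3, 3)).astype(x.dtype).copy())
    xp = ag.pad2d(x, (1, 1, 1, 1), mode="edge")
    gx = ag.conv2d(xp, wx, groups=C)
    gy = ag.conv2d(xp, wy, groups=C)
    return ag.sqrt(gx * gx + gy * gy + eps)


class MSEE(Module):
    def __init__(self, channels: int, dilations=(6, 12, 18), rng=None):
        super().__init__()
        C = channels
        # context path
        self.conv1x1 = Conv2d(C, C, 1, rng=rng)
        self.dilated = [Conv2d(C, C, 3, padding=d, dilation=d, rng=rng)
                        for d in dilations]
        self.ctx_norm = ChannelLayerNorm(C)
        self.q_proj = DepthwiseSeparableConv2d(C, C, 3, rng=rng)
        self.k_proj = DepthwiseSeparableConv2d(C, C, 3, rng=rng)
        self.v_proj = DepthwiseSeparableConv2d(C, C, 3, rng=rng)
        self.temperature = Parameter(np.ones(1, dtype=np.float32))
        self.out_proj = DepthwiseSeparableConv2d(C, C, 1, rng=rng)
        # edge path
        self.edge_pre = DepthwiseSeparableConv2d(C, C, 1, rng=rng)
        self.edge_bn = BatchNorm2d(C)
        self.edge_conv = DepthwiseSeparableConv2d(C, C, 3, rng=rng)
        self.edge_out = DepthwiseSeparableConv2d(C, C, 1, rng=rng)
        self.channels = C

    # ------------------------------------------------------------- left path
    def multiscale_context(self, x: Tensor) -> Tensor:
        """Sum of the 1x1 and dilated 3x3 branches, then normalization."""
        y = self.conv1x1(x)
        for conv in self.dilated:
            y = y + conv(x)
        return self.ctx_norm(y)

    def attention_map(self, y: Tensor) -> Tensor:
        """Channel-to-channel attention: softmax over the last axis of the
        temperature-scaled K-hat x Q-hat^T Gram matrix; rows sum to 1."""
        B, C, H, W = y.shape
        k = ag.reshape(self.k_proj(y), (B, C, H * W))
        q = ag.reshape(self.q_proj(y), (B, C, H * W))
        logits = ag.matmul(k, ag.transpose(q, (0, 2, 1))) * self.temperature
        return F.softmax(logits, axis=-1)            # (B, C, C)

    def transpose_attention(self, y: Tensor) -> Tensor:
        B, C, H, W = y.shape
        lam = self.attention_map(y)
        v = ag.reshape(self.v_proj(y), (B, C, H * W))
        agg = ag.reshape(ag.matmul(lam, v), (B, C, H, W))   # inverse reshape
        return self.out_proj(agg)

    def context_path(self, x: Tensor) -> Tensor:
        return self.transpose_attention(self.multiscale_context(x))

    # ------------------------------------------------------------ right path
    def edge_branch(self, x: Tensor) -> Tensor:
        t = self.edge_pre(x)
        t = ag.relu(self.edge_bn(sobel_magnitude(t)))
        x_edge = self.edge_conv(t)
        return self.edge_out(x + x_edge)

    def forward(self, x: Tensor) -> Tensor:
        return self.context_path(x) + self.edge_branch(x)
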