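"""Composite differentiable operations built from the autograd primitives."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor, as_tensor

__all__ = [
    "silu",
    "softmax",
    "layer_norm",
    "channel_layer_norm",
    "linear",
    "bilinear_resize",
    "adaptive_avg_pool2d",
    "avg_pool2d_3x3",
    "depth_to_space",
    "upsample2x_nearest",
]


def silu(x: Tensor) -> Tensor:
    return ag.mul(x, ag.sigmoid(x))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    x = as_tensor(x)
    m = np.max(x.data, axis=axis, keepdims=True)  # constant shift, no gradient
    e = ag.exp(x - m)
    return e / ag.tsum(e, axis=axis, keepdims=True)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis (channels-last layout)."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    xh = xc / ag.sqrt(var + eps)
    return xh * gamma + beta


def channel_layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the channel axis of a (B, C, H, W) map."""
    mu = x.mean(axis=1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=1, keepdims=True)
    xh = xc / ag.sqrt(var + eps)
    return xh * gamma.reshape((1, -1, 1, 1)) + beta.reshape((1, -1, 1, 1))


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w.T + b over the last axis; x (..., Cin), w (Cout, Cin)."""
    out = ag.matmul(x, ag.transpose(w, (1, 0)))
    if b is not None:
        out = out + b
    return out


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Bilinear interpolation as a dense (n_out, n_in) matrix (half-pixel centers)."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    if n_in == 1:
        M[:, 0] = 1.0
        return M
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = src - i0
    M[np.arange(n_out), i0] += 1.0 - frac
    M[np.arange(n_out), i1] += frac
    return M


def _pool_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Adaptive average pooling as a dense (n_out, n_in) averaging matrix."""
    M = np.zeros((n_out, n_in), dtype=dtype)
    for o in range(n_out):
        lo = (o * n_in) // n_out
        hi = -(-((o + 1) * n_in) // n_out)  # ceil
        M[o, lo:hi] = 1.0 / (hi - lo)
    return M


def _apply_axis_matrices(x: Tensor, Mh: np.ndarray, Mw: np.ndarray) -> Tensor:
    B, C, H, W = x.shape
    xr = ag.reshape(x, (B * C, H, W))
    y = ag.matmul(as_tensor(Mh), xr)               # (B*C, Ho, W)
    z = ag.matmul(y, as_tensor(Mw.T))              # (B*C, Ho, Wo)
    return ag.reshape(z, (B, C, Mh.shape[0], Mw.shape[0]))


def bilinear_resize(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    """Differentiable separable bilinear resize of a (B, C, H, W) map."""
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    if (Ho, Wo) == (H, W):
        return x
    dt = x.dtype
    return _apply_axis_matrices(x, _interp_matrix(H, Ho, dt), _interp_matrix(W, Wo, dt))


def adaptive_avg_pool2d(x: Tensor, out_hw: tuple[int, int]) -> Tensor:
    B, C, H, W = x.shape
    Ho, Wo = out_hw
    dt = x.dtype
    return _apply_axis_matrices(x, _pool_matrix(H, Ho, dt), _pool_matrix(W, Wo, dt))


def avg_pool2d_3x3(x: Tensor) -> Tensor:
    """3x3 average pooling, stride 1, zero padding 1 (channel preserving).

    Implemented as a fixed-weight depthwise convolution; the border average
    uses the zero-padded neighborhood divided by the true (clipped) window
    size so a spatially constant input is returned unchanged.
    """
    B, C, H, W = x.shape
    w = np.full((C, 1, 3, 3), 1.0, dtype=x.dtype)
    xp = ag.pad2d(x, (1, 1, 1, 1), mode="constant")
    s = ag.conv2d(xp, Tensor(w), stride=1, groups=C)
    ones = np.ones((1, 1, H, W), dtype=x.dtype)
    counts = ag.conv2d(Tensor(np.pad(ones, ((0, 0), (0, 0), (1, 1), (1, 1)))),
                       Tensor(np.ones((1, 1, 3, 3), dtype=x.dtype))).data
    return s * (1.0 / counts)


def depth_to_space(x: Tensor, r: int = 2) -> Tensor:
    """(B, C*r*r, H, W) -> (B, C, H*r, W*r); pairs with a 1x1 conv to form a
    2x2 stride-2 transposed convolution."""
    B, C4, H, W = x.shape
    C = C4 // (r * r)
    y = ag.reshape(x, (B, C, r, r, H, W))
    y = ag.transpose(y, (0, 1, 4, 2, 5, 3))
    return ag.reshape(y, (B, C, H * r, W * r))


def upsample2x_nearest(x: Tensor) -> Tensor:
    B, C, H, W = x.shape
    y = ag.reshape(x, (B, C, H, 1, W, 1))
    y = ag.concat([y, y], axis=3)
    y = ag.concat([y, y], axis=5)
    return ag.reshape(y, (B, C, 2 * H, 2 * W))
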