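"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  Only the primitives the segmentation network
needs are provided (elementwise math, matmul, reductions, cumsum, shape ops,
padding and a direct 2-D convolution).  Shapes broadcast like numpy; gradients
of broadcast operands are summed back to the operand's shape.

The engine is deliberately small and favours clarity over speed: convolutions
loop over kernel taps (at most 7x7 = 49 iterations) and contract with einsum,
which keeps memory bounded and is fast enough for desk-scale training runs.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import erf as _erf

__all__ = [
    "Tensor",
    "as_tensor",
    "add",
    "mul",
    "matmul",
    "exp",
    "log",
    "sqrt",
    "pow_scalar",
    "sigmoid",
    "tanh",
    "softplus",
    "relu",
    "gelu",
    "clip",
    "tsum",
    "cumsum",
    "reshape",
    "transpose",
    "flip",
    "concat",
    "getitem",
    "astype",
    "pad2d",
    "conv2d",
    "no_grad",
]


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph recording (inference / evaluation)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    # make ndarray <op> Tensor defer to Tensor's reflected operators
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GradMode.enabled
        self._parents: tuple = ()
        self._backward: Callable | None = None

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def item(self):
        return self.data.item()

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None, free_graph: bool = True):
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))

        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if free_graph:
                node._parents = ()
                node._backward = None

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, pow_scalar(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(pow_scalar(self, -1.0), other)

    def __pow__(self, p):
        return pow_scalar(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return tsum(self, axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        return transpose(self, axes)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    a = np.asarray(x, dtype=dtype)
    return Tensor(a)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to produce it."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


def _result(data, parents: Sequence[Tensor], backward: Callable | None) -> Tensor:
    req = _GradMode.enabled and any(p.requires_grad for p in parents)
    out = Tensor(data, requires_grad=req)
    if req:
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


def _accum(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    g = g.astype(t.data.dtype, copy=False)
    t.grad = g if t.grad is None else t.grad + g


# ------------------------------------------------------------------ primitives
def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accum(a, _unbroadcast(g, a.shape))
        _accum(b, _unbroadcast(g, b.shape))

    return _result(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accum(a, _unbroadcast(g * b.data, a.shape))
        _accum(b, _unbroadcast(g * a.data, b.shape))

    return _result(data, (a, b), backward)


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        ga = g @ b.data.swapaxes(-1, -2)
        gb = a.data.swapaxes(-1, -2) @ g
        _accum(a, _unbroadcast(ga, a.shape))
        _accum(b, _unbroadcast(gb, b.shape))

    return _result(data, (a, b), backward)


def exp(x) -> Tensor:
    x = as_tensor(x)
    data = np.exp(x.data)

    def backward(g):
        _accum(x, g * data)

    return _result(data, (x,), backward)


def log(x) -> Tensor:
    x = as_tensor(x)
    data = np.log(x.data)

    def backward(g):
        _accum(x, g / x.data)

    return _result(data, (x,), backward)


def sqrt(x) -> Tensor:
    x = as_tensor(x)
    data = np.sqrt(x.data)

    def backward(g):
        _accum(x, g * (0.5 / data))

    return _result(data, (x,), backward)


def pow_scalar(x, p: float) -> Tensor:
    x = as_tensor(x)
    p = float(p)
    data = x.data ** p

    def backward(g):
        _accum(x, g * p * x.data ** (p - 1.0))

    return _result(data, (x,), backward)


def sigmoid(x) -> Tensor:
    x = as_tensor(x)
    # numerically stable logistic
    data = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                    np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    data = data.astype(x.data.dtype, copy=False)

    def backward(g):
        _accum(x, g * data * (1.0 - data))

    return _result(data, (x,), backward)


def tanh(x) -> Tensor:
    x = as_tensor(x)
    data = np.tanh(x.data)

    def backward(g):
        _accum(x, g * (1.0 - data * data))

    return _result(data, (x,), backward)


def softplus(x) -> Tensor:
    x = as_tensor(x)
    data = np.logaddexp(0.0, x.data).astype(x.data.dtype, copy=False)

    def backward(g):
        s = 1.0 / (1.0 + np.exp(-x.data))
        _accum(x, g * s)

    return _result(data, (x,), backward)


def relu(x) -> Tensor:
    x = as_tensor(x)
    data = np.maximum(x.data, 0.0)

    def backward(g):
        _accum(x, g * (x.data > 0))

    return _result(data, (x,), backward)


def gelu(x) -> Tensor:
    """Exact (erf-based) Gaussian error linear unit."""
    x = as_tensor(x)
    cdf = 0.5 * (1.0 + _erf(x.data / np.sqrt(2.0)))
    data = (x.data * cdf).astype(x.data.dtype, copy=False)

    def backward(g):
        pdf = np.exp(-0.5 * x.data * x.data) / np.sqrt(2.0 * np.pi)
        _accum(x, g * (cdf + x.data * pdf))

    return _result(data, (x,), backward)


def clip(x, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the unclamped region."""
    x = as_tensor(x)
    data = np.clip(x.data, lo, hi)

    def backward(g):
        _accum(x, g * ((x.data >= lo) & (x.data <= hi)))

    return _result(data, (x,), backward)


def tsum(x, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    data = x.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            gx = np.broadcast_to(g, x.shape)
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, tuple(a % x.ndim for a in axes))
            gx = np.broadcast_to(g, x.shape)
        _accum(x, gx)

    return _result(data, (x,), backward)


def cumsum(x, axis: int) -> Tensor:
    x = as_tensor(x)
    data = np.cumsum(x.data, axis=axis)

    def backward(g):
        gx = np.flip(np.cumsum(np.flip(g, axis=axis), axis=axis), axis=axis)
        _accum(x, gx)

    return _result(data, (x,), backward)


def reshape(x, shape) -> Tensor:
    x = as_tensor(x)
    data = x.data.reshape(shape)

    def backward(g):
        _accum(x, g.reshape(x.shape))

    return _result(data, (x,), backward)


def transpose(x, axes) -> Tensor:
    x = as_tensor(x)
    axes = tuple(axes)
    data = x.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        _accum(x, g.transpose(inv))

    return _result(data, (x,), backward)


def flip(x, axis) -> Tensor:
    x = as_tensor(x)
    data = np.flip(x.data, axis=axis)

    def backward(g):
        _accum(x, np.flip(g, axis=axis))

    return _result(data, (x,), backward)


def concat(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accum(t, g[tuple(idx)])

    return _result(data, ts, backward)


def _is_basic_index(idx) -> bool:
    items = idx if isinstance(idx, tuple) else (idx,)
    return all(isinstance(i, (slice, int)) or i is Ellipsis or i is None
               for i in items)


def getitem(x, idx) -> Tensor:
    x = as_tensor(x)
    data = x.data[idx]
    basic = _is_basic_index(idx)

    def backward(g):
        gx = np.zeros_like(x.data)
        if basic:  # basic slices never alias, so direct assignment is safe
            gx[idx] = g
        else:
            np.add.at(gx, idx, g)
        _accum(x, gx)

    return _result(data, (x,), backward)


def astype(x, dtype) -> Tensor:
    x = as_tensor(x)
    dtype = np.dtype(dtype)
    data = x.data.astype(dtype, copy=False)

    def backward(g):
        _accum(x, g.astype(x.data.dtype, copy=False))

    return _result(data, (x,), backward)


def pad2d(x, pad: tuple, mode: str = "constant") -> Tensor:
    """Pad the last two axes of a 4-D tensor.

    pad = (top, bottom, left, right); mode 'constant' (zeros) or 'edge'
    (replicate, used by the Sobel operator so constants stay gradient-free
    at the borders).
    """
    x = as_tensor(x)
    t, b, l, r = pad
    B, C, H, W = x.shape
    row_idx = np.clip(np.arange(-t, H + b), 0, H - 1)
    col_idx = np.clip(np.arange(-l, W + r), 0, W - 1)
    if mode == "edge":
        data = x.data[:, :, row_idx][:, :, :, col_idx]

        def backward(g):
            g1 = np.zeros((B, C, H, W + l + r), dtype=g.dtype)
            np.add.at(g1, (slice(None), slice(None), row_idx), g)
            gx = np.zeros_like(x.data)
            np.add.at(gx, (slice(None), slice(None), slice(None), col_idx), g1)
            _accum(x, gx)

    elif mode == "constant":
        data = np.pad(x.data, ((0, 0), (0, 0), (t, b), (l, r)))

        def backward(g):
            _accum(x, g[:, :, t:t + H, l:l + W])

    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"unknown pad mode {mode!r}")

    return _result(data, (x,), backward)


def conv2d(x, w, bias=None, stride: int = 1, dilation: int = 1,
           groups: int = 1) -> Tensor:
    """Direct 2-D cross-correlation (no implicit padding; pad first).

    x: (B, Cin, H, W); w: (Cout, Cin//groups, kh, kw).  ``groups`` must be 1
    (dense) or Cin with Cout == Cin (depthwise) — the only two forms the
    network uses.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    depthwise = groups == Cin and Cin > 1
    if not depthwise and groups != 1:
        raise ValueError("conv2d supports groups == 1 or depthwise groups == Cin")
    if depthwise and (Cout != Cin or Cg != 1):
        raise ValueError("depthwise conv2d requires weight shape (C, 1, kh, kw)")
    Ho = (H - (kh - 1) * dilation - 1) // stride + 1
    Wo = (W - (kw - 1) * dilation - 1) // stride + 1
    if Ho <= 0 or Wo <= 0:
        raise ValueError("conv2d output would be empty; input too small for kernel")

    def tap_slice(i, j):
        return (slice(None), slice(None),
                slice(i * dilation, i * dilation + (Ho - 1) * stride + 1, stride),
                slice(j * dilation, j * dilation + (Wo - 1) * stride + 1, stride))

    out = np.zeros((B, Cout, Ho, Wo), dtype=x.data.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = x.data[tap_slice(i, j)]
            if depthwise:
                out += xs * w.data[:, 0, i, j][None, :, None, None]
            else:
                out += np.einsum("oc,bchw->bohw", w.data[:, :, i, j], xs, optimize=True)
    b_t = None
    if bias is not None:
        b_t = as_tensor(bias)
        out = out + b_t.data[None, :, None, None]

    def backward(g):
        if w.requires_grad:
            gw = np.zeros_like(w.data)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
        for i in range(kh):
            for j in range(kw):
                sl = tap_slice(i, j)
                xs = x.data[sl]
                if depthwise:
                    if w.requires_grad:
                        gw[:, 0, i, j] = (g * xs).sum(axis=(0, 2, 3))
                    if x.requires_grad:
                        gx[sl] += g * w.data[:, 0, i, j][None, :, None, None]
                else:
                    if w.requires_grad:
                        gw[:, :, i, j] = np.einsum("bohw,bchw->oc", g, xs, optimize=True)
                    if x.requires_grad:
                        gx[sl] += np.einsum("oc,bohw->bchw", w.data[:, :, i, j], g,
                                            optimize=True)
        if w.requires_grad:
            _accum(w, gw)
        if x.requires_grad:
            _accum(x, gx)
        if b_t is not None and b_t.requires_grad:
            _accum(b_t, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b_t is None else (x, w, b_t)
    return _result(out, parents, backward)
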