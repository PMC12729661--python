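"""Layer/module abstractions over the autograd engine.

Modules hold :class:`Parameter` tensors, recurse over children for parameter
collection, and carry a train/eval flag (batch-norm running statistics are the
only state that depends on it).  Construction is deterministic given the
``rng`` passed in; model builders thread a single seeded generator through
every layer.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from . import functional as F
from .autograd import Tensor

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "ModuleList",
    "Identity",
    "Linear",
    "Conv2d",
    "DepthwiseSeparableConv2d",
    "LayerNorm",
    "ChannelLayerNorm",
    "InstanceNorm2d",
    "BatchNorm2d",
]

DEFAULT_DTYPE = np.float32


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        self.requires_grad = True  # parameters ignore no_grad at creation


class Module:
    def __init__(self):
        self.training = True

    # -- parameter / module traversal -------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield f"{prefix}{name}", val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item
                    elif isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield from val.modules()
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        yield from item.modules()

    def num_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- state (de)serialization ------------------------------------------
    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, val in vars(self).items():
            if isinstance(val, BatchNorm2d):
                out[f"{name}.running_mean"] = val.running_mean.copy()
                out[f"{name}.running_var"] = val.running_var.copy()
            elif isinstance(val, Module):
                for k, v in val.state_dict().items():
                    if k.endswith(("running_mean", "running_var")):
                        out[f"{name}.{k}"] = v
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for k, v in item.state_dict().items():
                            if k.endswith(("running_mean", "running_var")):
                                out[f"{name}.{i}.{k}"] = v
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = [k for k in own if k not in state]
        if missing:
            raise ValueError(f"checkpoint missing parameters: {missing[:5]} ...")
        for name, p in own.items():
            arr = np.asarray(state[name])
            if arr.shape != p.data.shape:
                raise ValueError(
                    f"shape mismatch for {name}: checkpoint {arr.shape} vs model {p.data.shape}")
            p.data = arr.astype(p.data.dtype, copy=True)
        self._load_running_stats(state, "")

    def _load_running_stats(self, state: dict, prefix: str):
        for name, val in vars(self).items():
            if isinstance(val, BatchNorm2d):
                key = f"{prefix}{name}"
                if f"{key}.running_mean" in state:
                    val.running_mean = np.asarray(state[f"{key}.running_mean"]).astype(
                        val.running_mean.dtype)
                    val.running_var = np.asarray(state[f"{key}.running_var"]).astype(
                        val.running_var.dtype)
            elif isinstance(val, Module):
                val._load_running_stats(state, f"{prefix}{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        item._load_running_stats(state, f"{prefix}{name}.{i}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class ModuleList(Module):
    """Container registering a list of sub-modules (indexable, iterable)."""

    def __init__(self, items=()):
        super().__init__()
        self.items = list(items)

    def __iter__(self):
        return iter(self.items)

    def __getitem__(self, i):
        return self.items[i]

    def __len__(self):
        return len(self.items)

    def forward(self, *a, **k):  # pragma: no cover - containers are not called
        raise TypeError("ModuleList is not callable")


class Identity(Module):
    def forward(self, x):
        return x


def _kaiming(rng: np.random.Generator, shape, fan_in: int, dtype=DEFAULT_DTYPE):
    std = np.sqrt(2.0 / max(fan_in, 1))
    return rng.normal(0.0, std, size=shape).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if zero_init:
            w = np.zeros((out_features, in_features), dtype=DEFAULT_DTYPE)
        else:
            bound = np.sqrt(1.0 / in_features)
            w = rng.uniform(-bound, bound, size=(out_features, in_features)).astype(DEFAULT_DTYPE)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_features, dtype=DEFAULT_DTYPE)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Conv2d(Module):
    """Convolution with symmetric padding; groups 1 or depthwise."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 padding: int = 0, dilation: int = 1, groups: int = 1,
                 bias: bool = True, pad_mode: str = "constant",
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.groups, self.pad_mode = groups, pad_mode
        cg = in_ch // groups
        fan_in = cg * kernel * kernel
        if zero_init:
            w = np.zeros((out_ch, cg, kernel, kernel), dtype=DEFAULT_DTYPE)
        else:
            w = _kaiming(rng, (out_ch, cg, kernel, kernel), fan_in)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch, dtype=DEFAULT_DTYPE)) if bias else None

    def forward(self, x):
        if self.padding:
            p = self.padding
            x = ag.pad2d(x, (p, p, p, p), mode=self.pad_mode)
        return ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                         dilation=self.dilation, groups=self.groups)


class DepthwiseSeparableConv2d(Module):
    """Pointwise (1x1) composed with a depthwise kernel: W_P . W_D."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, padding: int | None = None,
                 dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None, zero_init: bool = False):
        super().__init__()
        if padding is None:
            padding = dilation * (kernel - 1) // 2
        self.depthwise = Conv2d(in_ch, in_ch, kernel, padding=padding, dilation=dilation,
                                groups=in_ch, bias=False, rng=rng)
        self.pointwise = Conv2d(in_ch, out_ch, 1, bias=bias, rng=rng, zero_init=zero_init)

    def forward(self, x):
        return self.pointwise(self.depthwise(x))


class LayerNorm(Module):
    """Normalization over the last axis (channels-last tensors)."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))

    def forward(self, x):
        return F.layer_norm(x, self.weight, self.bias, self.eps)


class ChannelLayerNorm(Module):
    """Layer normalization over the channel axis of a (B, C, H, W) map."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))

    def forward(self, x):
        return F.channel_layer_norm(x, self.weight, self.bias, self.eps)


class InstanceNorm2d(Module):
    """Per-sample, per-channel spatial normalization with affine terms."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))

    def forward(self, x):
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xh = xc / ag.sqrt(var + self.eps)
        return xh * self.weight.reshape((1, -1, 1, 1)) + self.bias.reshape((1, -1, 1, 1))


class BatchNorm2d(Module):
    """Batch statistics while training, running statistics at inference."""

    def __init__(self, dim: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(dim, dtype=DEFAULT_DTYPE))
        self.bias = Parameter(np.zeros(dim, dtype=DEFAULT_DTYPE))
        self.running_mean = np.zeros(dim, dtype=DEFAULT_DTYPE)
        self.running_var = np.ones(dim, dtype=DEFAULT_DTYPE)

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1)
                                 ).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1)
                                ).astype(self.running_var.dtype)
            xh = xc / ag.sqrt(var + self.eps)
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            var = self.running_var.reshape(1, -1, 1, 1)
            xh = (x - mu) * (1.0 / np.sqrt(var + self.eps))
        return xh * self.weight.reshape((1, -1, 1, 1)) + self.bias.reshape((1, -1, 1, 1))
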