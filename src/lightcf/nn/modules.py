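"""Layers and parameter management for the numpy runtime.

Weight initialisation draws from a seedable generator installed with
:func:`init_scope`, so building the same architecture under the same seed
yields bitwise-identical parameters regardless of platform.
"""
from __future__ import annotations

import contextlib
from collections import OrderedDict

import numpy as np

from . import functional as F
from . import tensor as T
from .tensor import Tensor

_INIT_RNG = np.random.default_rng(0)


@contextlib.contextmanager
def init_scope(seed: int):
    """Make parameter initialisation deterministic within the block."""
    global _INIT_RNG
    old = _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    try:
        yield
    finally:
        _INIT_RNG = old


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=T.default_dtype()), requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for pname, p in mod._params.items():
                yield (f"{name}.{pname}" if name else pname), p

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, mod in self.named_modules(prefix):
            for bname in mod._buffers:
                yield (f"{name}.{bname}" if name else bname), mod

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- (de)serialisation --------------------------------------------------
    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, mod in self.named_buffers():
            bname = name.split(".")[-1]
            out[name] = np.asarray(mod._buffers[bname]).copy()
        return out

    def load_state_dict(self, state: dict):
        mine = dict(self.named_parameters())
        missing = set(mine) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)[:5]} ...")
        for name, p in mine.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()
        for name, mod in self.named_buffers():
            if name in state:
                bname = name.split(".")[-1]
                mod._set_buffer(bname, np.asarray(state[name]).copy())
        return self

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def forward(self, x):
        for m in self._modules.values():
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._modules.values())


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)

    def __iter__(self):
        return iter(self._modules.values())

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[str(i)]

    def forward(self, *a):  # pragma: no cover - containers are not called
        raise NotImplementedError


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class GELU(Module):
    def forward(self, x):
        return T.gelu(x)


class SiLU(Module):
    def forward(self, x):
        return T.silu(x)


class Sigmoid(Module):
    def forward(self, x):
        return T.sigmoid(x)


class Conv2d(Module):
    """Stride-1 convolution; padding defaults to "same"."""

    def __init__(self, cin, cout, kernel_size, padding="same", dilation=1,
                 groups=1, bias=True):
        super().__init__()
        if cin < 1 or cout < 1:
            raise ValueError("channel counts must be positive")
        k = int(kernel_size)
        if padding == "same":
            padding = dilation * (k - 1) // 2
        self.cin, self.cout, self.k = cin, cout, k
        self.padding, self.dilation, self.groups = padding, dilation, groups
        fan_in = (cin // groups) * k * k
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(_INIT_RNG.normal(0.0, std, (cout, cin // groups, k, k)))
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, padding=self.padding,
                        dilation=self.dilation, groups=self.groups)


class CausalConv1d(Module):
    """Depth-wise causal conv over (B, L, C) sequences."""

    def __init__(self, channels, kernel_size=4, bias=True):
        super().__init__()
        bound = 1.0 / np.sqrt(kernel_size)
        self.weight = Parameter(_INIT_RNG.uniform(-bound, bound, (channels, kernel_size)))
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return F.causal_conv1d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, fin, fout, bias=True):
        super().__init__()
        bound = 1.0 / np.sqrt(fin)
        self.weight = Parameter(_INIT_RNG.uniform(-bound, bound, (fin, fout)))
        self.bias = Parameter(np.zeros(fout)) if bias else None

    def forward(self, x):
        y = T.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class BatchNorm2d(Module):
    def __init__(self, channels, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=T.default_dtype()))
        self.register_buffer("running_var", np.ones(channels, dtype=T.default_dtype()))

    def forward(self, x):
        if self.training and T.grad_enabled():
            y, m, v = F.batch_norm_train(x, self.weight, self.bias, self.eps)
            nper = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = v * nper / max(nper - 1, 1)
            self._set_buffer("running_mean", (1 - self.momentum) * self.running_mean
                             + self.momentum * m)
            self._set_buffer("running_var", (1 - self.momentum) * self.running_var
                             + self.momentum * unbiased)
            return y
        rm = self.running_mean.reshape(1, -1, 1, 1)
        rv = self.running_var.reshape(1, -1, 1, 1)
        scale = (self.weight.reshape(1, -1, 1, 1)
                 * (1.0 / np.sqrt(rv + self.eps)))
        return x * scale + (self.bias.reshape(1, -1, 1, 1) - rm * scale)


class LayerNorm(Module):
    """Normalises the trailing feature axis of (..., C)."""

    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        m = x.mean(axis=-1, keepdims=True)
        xc = x - m
        v = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * T.pow_(v + self.eps, -0.5) * self.weight + self.bias


class MaxPool2d(Module):
    def forward(self, x):
        return F.max_pool2x2(x)


class UpsampleBilinear2x(Module):
    def forward(self, x):
        return F.upsample_bilinear_2x(x)
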