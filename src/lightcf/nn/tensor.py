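"""Array autodiff core.

A small reverse-mode automatic differentiation engine over numpy arrays.
Every operation used by the segmentation network is stride-1 and
shape-regular, which keeps the op set small: broadcasting arithmetic,
matmul, reductions, shape ops and a handful of pointwise nonlinearities.
Convolutions, pooling and the selective scan live in
:mod:`lightcf.nn.functional` and :mod:`lightcf.nn.scan` and plug into the
same graph through :func:`make_op`.
"""
from __future__ import annotations

import contextlib

import numpy as np
from scipy import special as _sp

_DEFAULT_DTYPE = np.float32
_GRAD_ENABLED = True


def default_dtype():
    return _DEFAULT_DTYPE


def set_default_dtype(dtype) -> None:
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


@contextlib.contextmanager
def autocast_dtype(dtype):
    """Temporarily change the dtype newly created parameters use."""
    global _DEFAULT_DTYPE
    old = _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type
    try:
        yield
    finally:
        _DEFAULT_DTYPE = old


def grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / metric evaluation)."""
    global _GRAD_ENABLED
    old = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = old


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    # numpy must defer to the reflected operators below instead of
    # broadcasting elementwise over a Tensor operand.
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        if self.data.dtype == np.float64 and _DEFAULT_DTYPE == np.float32:
            # Literals default to float64; keep the graph in one dtype.
            self.data = self.data.astype(_DEFAULT_DTYPE)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = ()

    # -- basic introspection ------------------------------------------------
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

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.data.dtype}, grad={self.requires_grad})"

    # -- autograd -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # Free graph bookkeeping as we go.
                node._backward = None
                node._prev = ()

    def _accumulate(self, grad: np.ndarray) -> None:
        # Copy-on-write: the first gradient is stored as-is (most nodes have a
        # single consumer); a second accumulation allocates a fresh array so a
        # buffer shared between parents is never mutated in place.
        grad = _unbroadcast(np.asarray(grad, dtype=self.data.dtype), self.data.shape)
        if self.grad is None:
            self.grad = grad
        else:
            self.grad = self.grad + grad

    # -- operators ----------------------------------------------------------
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
            return mul(self, pow_(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __rtruediv__(self, other):
        return mul(pow_(self, -1.0), other)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    # convenience method forms
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes or None)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def make_op(data: np.ndarray, parents: tuple, backward) -> Tensor:
    """Create a graph node; `backward(grad)` must call `_accumulate` on parents."""
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if _GRAD_ENABLED and any(p.requires_grad or p._prev for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


# -- primitive ops ----------------------------------------------------------
def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        a._accumulate(g)
        b._accumulate(g)

    return make_op(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        a._accumulate(g * b.data)
        b._accumulate(g * a.data)

    return make_op(out_data, (a, b), backward)


def pow_(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return make_op(out_data, (a,), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if b.data.ndim == 2 and a.data.ndim >= 2:
            a._accumulate(g @ b.data.T)
            ga = a.data.reshape(-1, a.data.shape[-1])
            b._accumulate(ga.T @ g.reshape(-1, g.shape[-1]))
        else:  # general batched case
            a._accumulate(g @ np.swapaxes(b.data, -1, -2))
            b._accumulate(np.swapaxes(a.data, -1, -2) @ g)

    return make_op(out_data, (a, b), backward)


def exp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * out_data)

    return make_op(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return make_op(out_data, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    out_data = _sp.expit(a.data)

    def backward(g):
        a._accumulate(g * out_data * (1.0 - out_data))

    return make_op(out_data, (a,), backward)


def tanh(a):
    a = as_tensor(a)
    out_data = np.tanh(a.data)

    def backward(g):
        a._accumulate(g * (1.0 - out_data * out_data))

    return make_op(out_data, (a,), backward)


def erf(a):
    a = as_tensor(a)
    out_data = _sp.erf(a.data)

    def backward(g):
        a._accumulate(g * (2.0 / np.sqrt(np.pi)) * np.exp(-a.data * a.data))

    return make_op(out_data, (a,), backward)


def relu(a):
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0)

    def backward(g):
        a._accumulate(g * (a.data > 0))

    return make_op(out_data, (a,), backward)


def softplus(a, beta: float = 1.0):
    """log(1+exp(x)), numerically stable; derivative is the sigmoid."""
    a = as_tensor(a)
    z = beta * a.data
    out_data = (np.logaddexp(0.0, z) / beta).astype(a.data.dtype)

    def backward(g):
        a._accumulate(g * _sp.expit(z))

    return make_op(out_data, (a,), backward)


def clip(a, lo: float, hi: float):
    """Clamp with pass-through gradient strictly inside the bounds."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def backward(g):
        a._accumulate(g * mask)

    return make_op(out_data, (a,), backward)


def sum_(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accumulate(np.broadcast_to(g, a.data.shape))

    return make_op(out_data, (a,), backward)


def mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
    return mul(sum_(a, axis, keepdims), 1.0 / float(n))


def max_(a, axis: int, keepdims=False):
    a = as_tensor(a)
    idx = np.argmax(a.data, axis=axis)
    out_data = np.take_along_axis(a.data, np.expand_dims(idx, axis), axis=axis)
    if not keepdims:
        out_data = np.squeeze(out_data, axis)

    def backward(g):
        if not keepdims:
            g = np.expand_dims(g, axis)
        buf = np.zeros_like(a.data)
        np.put_along_axis(buf, np.expand_dims(idx, axis), g, axis=axis)
        a._accumulate(buf)

    return make_op(out_data, (a,), backward)


def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(a.data.shape))

    return make_op(out_data, (a,), backward)


def transpose(a, axes=None):
    a = as_tensor(a)
    out_data = np.transpose(a.data, axes)
    inv = None if axes is None else np.argsort(axes)

    def backward(g):
        a._accumulate(np.transpose(g, inv))

    return make_op(out_data, (a,), backward)


def getitem(a, idx):
    a = as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        buf = np.zeros_like(a.data)
        np.add.at(buf, idx, g)
        a._accumulate(buf)

    return make_op(out_data, (a,), backward)


def concat(tensors, axis: int = 0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return make_op(out_data, tuple(tensors), backward)


def where_const(cond: np.ndarray, a, b):
    """Select between two tensors with a constant boolean mask."""
    a, b = as_tensor(a), as_tensor(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        a._accumulate(np.where(cond, g, 0.0))
        b._accumulate(np.where(cond, 0.0, g))

    return make_op(out_data, (a, b), backward)


# -- composites -------------------------------------------------------------
def gelu(a):
    """Exact (erf-based) Gaussian error linear unit."""
    return mul(mul(a, 0.5), add(erf(mul(a, 1.0 / np.sqrt(2.0))), 1.0))


def silu(a):
    return mul(a, sigmoid(a))


def softmax(a, axis: int):
    a = as_tensor(a)
    shifted = add(a, -a.data.max(axis=axis, keepdims=True))
    e = exp(shifted)
    return mul(e, pow_(sum_(e, axis, keepdims=True), -1.0))
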