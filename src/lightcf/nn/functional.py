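"""Structured ops: convolutions, pooling, resampling.

All convolutions in the network are stride-1 with "same" padding
(downsampling is done by max-pooling), which allows a simple and fast
shift-and-matmul implementation: a k x k convolution is a sum of k^2
channel-mixing matrix products over shifted views of the padded input.
The backward pass reuses the same views, so no im2col buffer is kept.
"""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, as_tensor, make_op

__all__ = [
    "conv2d",
    "causal_conv1d",
    "max_pool2x2",
    "upsample_bilinear_2x",
    "global_avg_pool",
    "global_max_pool",
]


def _tap_view(xp: np.ndarray, i: int, j: int, dil: int, oh: int, ow: int) -> np.ndarray:
    return xp[:, :, i * dil:i * dil + oh, j * dil:j * dil + ow]


def _build_col(xcl: np.ndarray, kh: int, kw: int, dil: int, oh: int, ow: int) -> np.ndarray:
    """im2col from a channels-last padded input; (B*oh*ow, kh*kw*Cin) layout."""
    b, _, _, ci = xcl.shape
    col = np.empty((b, oh, ow, kh * kw, ci), dtype=xcl.dtype)
    t = 0
    for i in range(kh):
        for j in range(kw):
            col[:, :, :, t, :] = xcl[:, i * dil:i * dil + oh, j * dil:j * dil + ow, :]
            t += 1
    return col.reshape(b * oh * ow, kh * kw * ci)


def _conv2d_gemm(x, weight, bias, padding, dilation, oh, ow):
    """Ungrouped stride-1 convolution as one matrix product (channels-last im2col)."""
    b, cin = x.shape[:2]
    cout, _, kh, kw = weight.shape
    one_by_one = kh == 1 and kw == 1
    # Single permuted copy into channels-last; every later copy is contiguous.
    xcl = np.pad(x.data.transpose(0, 2, 3, 1),
                 ((0, 0), (padding, padding), (padding, padding), (0, 0)))
    col = xcl.reshape(-1, cin) if one_by_one else _build_col(xcl, kh, kw, dilation, oh, ow)
    wmat = weight.data.transpose(2, 3, 1, 0).reshape(kh * kw * cin, cout)
    out2d = col @ wmat
    if bias is not None:
        out2d += bias.data
    out = out2d.reshape(b, oh, ow, cout).transpose(0, 3, 1, 2).copy()

    def backward(grad):
        gcl = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, cout)
        gw = col.T @ gcl
        weight._accumulate(gw.reshape(kh, kw, cin, cout).transpose(3, 2, 0, 1))
        if x.requires_grad or x._prev:  # leaves (input images) need no gradient
            gcol = (gcl @ wmat.T).reshape(b, oh, ow, kh * kw, cin)
            gxcl = np.zeros_like(xcl)
            t = 0
            for i in range(kh):
                for j in range(kw):
                    gxcl[:, i * dilation:i * dilation + oh,
                         j * dilation:j * dilation + ow, :] += gcol[:, :, :, t, :]
                    t += 1
            if padding:
                gxcl = gxcl[:, padding:-padding, padding:-padding, :]
            x._accumulate(gxcl.transpose(0, 3, 1, 2))
        if bias is not None:
            bias._accumulate(gcl.sum(axis=0))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_op(out, parents, backward)


def conv2d(x, weight, bias=None, padding: int = 0, dilation: int = 1, groups: int = 1):
    """2-D cross-correlation, stride 1.

    Parameters
    ----------
    x : Tensor, shape (B, Cin, H, W)
    weight : Tensor, shape (Cout, Cin // groups, kh, kw)
    bias : Tensor of shape (Cout,) or None
    """
    x, weight = as_tensor(x), as_tensor(weight)
    b, cin, h, w = x.shape
    cout, cg, kh, kw = weight.shape
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError(f"kernel sizes must be odd, got {kh}x{kw}")
    if cin != cg * groups or cout % groups:
        raise ValueError(
            f"channel/group mismatch: cin={cin}, weight expects {cg}x{groups} groups")
    oh = h + 2 * padding - dilation * (kh - 1)
    ow = w + 2 * padding - dilation * (kw - 1)
    if oh < 1 or ow < 1:
        raise ValueError("input smaller than the (dilated) kernel")

    if groups == 1:
        return _conv2d_gemm(x, weight, bias, padding, dilation, oh, ow)

    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    wd = weight.data
    out = np.zeros((b, cout, oh, ow), dtype=x.data.dtype)
    depthwise = groups == cin and cg == 1 and cout == cin

    for i in range(kh):
        for j in range(kw):
            xs = _tap_view(xp, i, j, dilation, oh, ow)
            if depthwise:
                out += wd[:, 0, i, j][None, :, None, None] * xs
            elif groups == 1:
                out += np.tensordot(xs, wd[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
            else:
                og = cout // groups
                for g in range(groups):
                    xg = xs[:, g * cg:(g + 1) * cg]
                    wg = wd[g * og:(g + 1) * og, :, i, j]
                    out[:, g * og:(g + 1) * og] += np.tensordot(
                        xg, wg, axes=([1], [1])).transpose(0, 3, 1, 2)
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(grad):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(wd)
        for i in range(kh):
            for j in range(kw):
                xs = _tap_view(xp, i, j, dilation, oh, ow)
                gxs = _tap_view(gxp, i, j, dilation, oh, ow)
                if depthwise:
                    gw[:, 0, i, j] = np.einsum("bchw,bchw->c", grad, xs)
                    gxs += wd[:, 0, i, j][None, :, None, None] * grad
                elif groups == 1:
                    gw[:, :, i, j] = np.tensordot(grad, xs, axes=([0, 2, 3], [0, 2, 3]))
                    gxs += np.tensordot(grad, wd[:, :, i, j], axes=([1], [0])).transpose(0, 3, 1, 2)
                else:
                    og = cout // groups
                    for g in range(groups):
                        go = grad[:, g * og:(g + 1) * og]
                        xg = xs[:, g * cg:(g + 1) * cg]
                        gw[g * og:(g + 1) * og, :, i, j] = np.tensordot(
                            go, xg, axes=([0, 2, 3], [0, 2, 3]))
                        gxs[:, g * cg:(g + 1) * cg] += np.tensordot(
                            go, wd[g * og:(g + 1) * og, :, i, j],
                            axes=([1], [0])).transpose(0, 3, 1, 2)
        weight._accumulate(gw)
        if padding:
            x._accumulate(gxp[:, :, padding:-padding, padding:-padding])
        else:
            x._accumulate(gxp)
        if bias is not None:
            bias._accumulate(grad.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_op(out, parents, backward)


def causal_conv1d(x, weight, bias=None):
    """Depth-wise causal 1-D convolution over a (B, L, C) sequence.

    `weight` has shape (C, K); position t sees inputs t-K+1 .. t
    (left zero padding), so the output is strictly causal.
    """
    x, weight = as_tensor(x), as_tensor(weight)
    b, L, c = x.shape
    cw, k = weight.shape
    if cw != c:
        raise ValueError(f"weight channels {cw} != input channels {c}")
    xp = np.pad(x.data, ((0, 0), (k - 1, 0), (0, 0)))
    out = np.zeros_like(x.data)
    for t in range(k):
        out += weight.data[:, t][None, None, :] * xp[:, t:t + L, :]
    if bias is not None:
        out += bias.data[None, None, :]

    def backward(grad):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(weight.data)
        for t in range(k):
            gw[:, t] = np.einsum("blc,blc->c", grad, xp[:, t:t + L, :])
            gxp[:, t:t + L, :] += weight.data[:, t][None, None, :] * grad
        x._accumulate(gxp[:, k - 1:, :])
        weight._accumulate(gw)
        if bias is not None:
            bias._accumulate(grad.sum(axis=(0, 1)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_op(out, parents, backward)


def max_pool2x2(x):
    """2x2 max pooling with stride 2; H and W must be even."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 needs even spatial dims, got {h}x{w}")
    win = x.data.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    win = win.reshape(b, c, h // 2, w // 2, 4)
    idx = np.argmax(win, axis=-1)
    out = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(grad):
        gwin = np.zeros_like(win)
        np.put_along_axis(gwin, idx[..., None], grad[..., None], axis=-1)
        g = gwin.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(g.reshape(b, c, h, w))

    return make_op(out, (x,), backward)


_interp_cache: dict[tuple, np.ndarray] = {}


def _interp_matrix(n_out: int, n_in: int, dtype) -> np.ndarray:
    """Dense 1-D linear interpolation matrix, half-pixel-centre convention."""
    key = (n_out, n_in, np.dtype(dtype).str)
    m = _interp_cache.get(key)
    if m is None:
        m = np.zeros((n_out, n_in), dtype=dtype)
        scale = n_in / n_out
        src = (np.arange(n_out) + 0.5) * scale - 0.5
        i0 = np.clip(np.floor(src).astype(int), 0, n_in - 1)
        i1 = np.clip(i0 + 1, 0, n_in - 1)
        frac = np.clip(src - np.floor(src), 0.0, 1.0)
        frac[src < 0] = 0.0
        m[np.arange(n_out), i0] += 1.0 - frac
        m[np.arange(n_out), i1] += frac
        _interp_cache[key] = m
    return m


def upsample_bilinear_2x(x):
    """Bilinear 2x upsampling (separable, half-pixel centres)."""
    x = as_tensor(x)
    b, c, h, w = x.shape
    mh = _interp_matrix(2 * h, h, x.data.dtype)
    mw = _interp_matrix(2 * w, w, x.data.dtype)
    tmp = np.tensordot(mh, x.data, axes=([1], [2]))          # (2H, B, C, W)
    out = np.tensordot(tmp, mw, axes=([3], [1]))             # (2H, B, C, 2W)
    out = out.transpose(1, 2, 0, 3).copy()

    def backward(grad):
        g = grad.transpose(2, 0, 1, 3)                        # (2H, B, C, 2W)
        g = np.tensordot(g, mw, axes=([3], [0]))              # (2H, B, C, W)
        g = np.tensordot(mh, g, axes=([0], [0]))              # (H, B, C, W) via Mh^T
        x._accumulate(g.transpose(1, 2, 0, 3))

    return make_op(out, (x,), backward)


def batch_norm_train(x, gamma, beta, eps: float):
    """Fused training-mode batch normalisation over (B, C, H, W).

    Returns (y, batch_mean, biased_batch_var); the backward pass uses the
    closed-form expression instead of the composed elementwise graph.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    n = x.shape[0] * x.shape[2] * x.shape[3]
    m = x.data.mean(axis=axes)
    xc = x.data - m[None, :, None, None]
    v = np.mean(xc * xc, axis=axes)
    ivar = 1.0 / np.sqrt(v + eps)
    xhat = xc * ivar[None, :, None, None]
    y = xhat * gamma.data[None, :, None, None] + beta.data[None, :, None, None]

    def backward(g):
        dgamma = np.einsum("bchw,bchw->c", g, xhat)
        dbeta = g.sum(axis=axes)
        gamma._accumulate(dgamma)
        beta._accumulate(dbeta)
        if x.requires_grad or x._prev:
            k = (gamma.data * ivar / n)[None, :, None, None]
            x._accumulate(k * (n * g - dbeta[None, :, None, None]
                               - xhat * dgamma[None, :, None, None]))

    out = make_op(y, (x, gamma, beta), backward)
    return out, m, v


def global_avg_pool(x):
    """(B, C, H, W) -> (B, C) spatial mean."""
    return x.mean(axis=(2, 3))


def global_max_pool(x):
    from .tensor import max_
    return max_(max_(x, axis=3), axis=2)
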