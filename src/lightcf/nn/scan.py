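"""Selective state-space scan.

The recurrence (per batch item, channel ch and state index n):

    h_t = exp(dt_t * A) * h_{t-1} + dt_t * B_t * u_t        (h_0 = 0)
    y_t = sum_n C_t[n] * h_t[n] + D * u_t

with input-dependent step size dt, input projection B_t and output
projection C_t ("selective" parameters), a per-channel negative state
matrix A and a skip gain D.  The scan is strictly causal.  Forward and
backward passes are hand-derived sequential loops compiled with numba;
an O(L*N) pure-python reference lives in the test suite.
"""
from __future__ import annotations

import numpy as np
from numba import njit

from .tensor import as_tensor, make_op


@njit(cache=True, fastmath=True)
def _scan_forward(u, dt, A, B, C, D, hist, store):
    b, L, c = u.shape
    n = A.shape[1]
    y = np.zeros((b, L, c), dtype=u.dtype)
    for bi in range(b):
        h = np.zeros((c, n), dtype=u.dtype)
        for t in range(L):
            for ch in range(c):
                acc = 0.0
                for s in range(n):
                    h[ch, s] = (np.exp(dt[bi, t, ch] * A[ch, s]) * h[ch, s]
                                + dt[bi, t, ch] * B[bi, t, s] * u[bi, t, ch])
                    acc += C[bi, t, s] * h[ch, s]
                y[bi, t, ch] = acc + D[ch] * u[bi, t, ch]
            if store:
                hist[bi, t] = h
    return y


@njit(cache=True, fastmath=True)
def _scan_backward(gy, u, dt, A, B, C, D, hist):
    b, L, c = u.shape
    n = A.shape[1]
    gu = np.zeros_like(u)
    gdt = np.zeros_like(dt)
    gA = np.zeros_like(A)
    gB = np.zeros_like(B)
    gC = np.zeros_like(C)
    gD = np.zeros_like(D)
    for bi in range(b):
        dh = np.zeros((c, n), dtype=u.dtype)
        for t in range(L - 1, -1, -1):
            for ch in range(c):
                gD[ch] += gy[bi, t, ch] * u[bi, t, ch]
                g = gy[bi, t, ch]
                d = dt[bi, t, ch]
                uu = u[bi, t, ch]
                acc_u = D[ch] * g
                acc_dt = 0.0
                for s in range(n):
                    gC[bi, t, s] += hist[bi, t, ch, s] * g
                    dhs = dh[ch, s] + C[bi, t, s] * g
                    hprev = hist[bi, t - 1, ch, s] if t > 0 else 0.0
                    a = np.exp(d * A[ch, s])
                    acc_dt += dhs * (hprev * a * A[ch, s] + B[bi, t, s] * uu)
                    gA[ch, s] += dhs * hprev * a * d
                    gB[bi, t, s] += dhs * d * uu
                    acc_u += dhs * d * B[bi, t, s]
                    dh[ch, s] = dhs * a
                gu[bi, t, ch] = acc_u
                gdt[bi, t, ch] = acc_dt
    return gu, gdt, gA, gB, gC, gD


def selective_scan(u, dt, A, B, C, D):
    """Run the selective scan over a (B, L, C) sequence.

    Parameters
    ----------
    u : Tensor (batch, L, C) input sequence
    dt : Tensor (batch, L, C) per-step, per-channel step sizes, all > 0
    A : Tensor (C, N) state transition (negative for stability)
    B, C : Tensor (batch, L, N) input/output projections per step
    D : Tensor (C,) skip gain
    """
    u, dt, A, B, C, D = map(as_tensor, (u, dt, A, B, C, D))
    if np.any(dt.data <= 0):
        raise ValueError("selective_scan requires strictly positive step sizes dt")
    bsz, L, c = u.shape
    n = A.shape[1]
    from .tensor import grad_enabled
    need_grad = grad_enabled() and any(
        t.requires_grad or t._prev for t in (u, dt, A, B, C, D))
    hist = np.zeros((bsz, L, c, n) if need_grad else (1, 1, c, n), dtype=u.data.dtype)
    y = _scan_forward(np.ascontiguousarray(u.data), np.ascontiguousarray(dt.data),
                      np.ascontiguousarray(A.data), np.ascontiguousarray(B.data),
                      np.ascontiguousarray(C.data), np.ascontiguousarray(D.data),
                      hist, need_grad)

    def backward(grad):
        gu, gdt, gA, gB, gC, gD = _scan_backward(
            np.ascontiguousarray(grad), u.data, dt.data, A.data, B.data, C.data,
            D.data, hist)
        u._accumulate(gu)
        dt._accumulate(gdt)
        A._accumulate(gA)
        B._accumulate(gB)
        C._accumulate(gC)
        D._accumulate(gD)

    return make_op(y, (u, dt, A, B, C, D), backward)
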