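import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def f64():
    """Run the block under double precision (tight-tolerance oracles)."""
    from lightcf.nn import tensor as T
    with T.autocast_dtype(np.float64):
        yield np.float64


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def numeric_gradient(fn, arr, eps=1e-6):
    """Central finite differences of a scalar-valued fn at arr."""
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        ap, am = arr.copy(), arr.copy()
        ap[i] += eps
        am[i] -= eps
        g[i] = (fn(ap) - fn(am)) / (2 * eps)
    return g


@pytest.fixture
def gradcheck():
    return numeric_gradient


def naive_selective_scan(u, dt, A, B, C, D):
    """Independent O(L*N) reference recurrence for the selective scan."""
    b, L, c = u.shape
    n = A.shape[1]
    y = np.zeros_like(u)
    for bi in range(b):
        h = np.zeros((c, n), dtype=u.dtype)
        for t in range(L):
            a_bar = np.exp(dt[bi, t][:, None] * A)            # (c, n)
            h = a_bar * h + dt[bi, t][:, None] * B[bi, t][None, :] * u[bi, t][:, None]
            y[bi, t] = h @ C[bi, t] + D * u[bi, t]
    return y


@pytest.fixture
def scan_oracle():
    return naive_selective_scan


def dense_conv2d(x, w, bias=None, dilation=1, padding=0):
    """Brute-force dense correlation oracle (nested python loops)."""
    b, ci, h, wdt = x.shape
    co, cg, kh, kw = w.shape
    groups = ci // cg
    og = co // groups
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = h + 2 * padding - dilation * (kh - 1)
    ow = wdt + 2 * padding - dilation * (kw - 1)
    out = np.zeros((b, co, oh, ow), dtype=x.dtype)
    for bi in range(b):
        for o in range(co):
            g = o // og
            for y in range(oh):
                for xx in range(ow):
                    acc = 0.0
                    for c in range(cg):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (w[o, c, i, j]
                                        * xp[bi, g * cg + c,
                                             y + i * dilation, xx + j * dilation])
                    out[bi, o, y, xx] = acc
            if bias is not None:
                out[bi, o] += bias[o]
    return out


@pytest.fixture
def conv_oracle():
    return dense_conv2d
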