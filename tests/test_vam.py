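"""Visual attention Mamba skip module: raster flattening, the selective
scan against a naive recurrence oracle, causality, and the gated block."""
import numpy as np
import pytest

import lightcf.nn as nn
from lightcf.nn.scan import selective_scan
from lightcf.vam import VAM, MambaBlock, flatten_to_sequence, reshape_to_map


def _random_scan_instance(rng, b=1, L=16, c=3, n=4, dtype=np.float64):
    u = rng.normal(size=(b, L, c)).astype(dtype)
    dt = rng.uniform(0.05, 1.0, (b, L, c)).astype(dtype)
    A = -rng.uniform(0.2, 2.0, (c, n)).astype(dtype)
    B = rng.normal(size=(b, L, n)).astype(dtype)
    C = rng.normal(size=(b, L, n)).astype(dtype)
    D = rng.normal(size=c).astype(dtype)
    return u, dt, A, B, C, D


class TestFlattenRoundTrip:
    def test_round_trip_identity(self, f64, rng):
        x = rng.normal(size=(2, 5, 4, 6))
        seq = flatten_to_sequence(nn.Tensor(x))
        back = reshape_to_map(seq, 4, 6)
        np.testing.assert_array_equal(back.data, x)

    def test_raster_order_convention(self, f64):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])[None, None]
        seq = flatten_to_sequence(nn.Tensor(x)).data
        np.testing.assert_array_equal(seq[0, :, 0], [1, 2, 3, 4])

    def test_length_is_h_times_w(self, f64, rng):
        seq = flatten_to_sequence(nn.Tensor(rng.normal(size=(1, 2, 16, 16))))
        assert seq.shape[1] == 256

    def test_wrong_length_rejected(self, f64, rng):
        with pytest.raises(ValueError):
            reshape_to_map(nn.Tensor(rng.normal(size=(1, 6, 2))), 2, 2)


class TestSelectiveScan:
    def test_zero_output_projection_reduces_to_skip_path(self, f64, rng):
        u, dt, A, B, C, D = _random_scan_instance(rng)
        C = np.zeros_like(C)
        y = selective_scan(*map(nn.Tensor, (u, dt, A, B, C, D))).data
        np.testing.assert_allclose(y, D * u, rtol=1e-12)

    def test_memoryless_limit_matches_hand_computation(self, f64, rng):
        # A -> -inf makes exp(dt*A) ~ 0: y_t = C_t . (dt_t B_t u_t) + D u_t,
        # hand-checkable on a length-3 scalar sequence.
        u, dt, A, B, C, D = _random_scan_instance(rng, L=3, c=1, n=1)
        A = np.full_like(A, -1e4)
        y = selective_scan(*map(nn.Tensor, (u, dt, A, B, C, D))).data
        expect = C * (dt * B * u) + D * u
        np.testing.assert_allclose(y, expect, rtol=1e-10)

    def test_matches_naive_recurrence_on_random_instances(self, f64, rng, scan_oracle):
        for _ in range(100):
            inst = _random_scan_instance(rng, L=16, c=3, n=4)
            y = selective_scan(*map(nn.Tensor, inst)).data
            ref = scan_oracle(*inst)
            np.testing.assert_allclose(y, ref, rtol=1e-5, atol=1e-10)

    def test_causality_under_perturbation(self, f64, rng):
        u, dt, A, B, C, D = _random_scan_instance(rng, L=12, c=2, n=3)
        y0 = selective_scan(*map(nn.Tensor, (u, dt, A, B, C, D))).data
        t_perturb = 7
        u2 = u.copy()
        u2[0, t_perturb] += 10.0
        y1 = selective_scan(*map(nn.Tensor, (u2, dt, A, B, C, D))).data
        np.testing.assert_array_equal(y0[0, :t_perturb], y1[0, :t_perturb])
        assert np.any(y0[0, t_perturb:] != y1[0, t_perturb:])

    def test_nonpositive_dt_rejected(self, f64, rng):
        u, dt, A, B, C, D = _random_scan_instance(rng)
        dt[0, 0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            selective_scan(*map(nn.Tensor, (u, dt, A, B, C, D)))

    def test_gradient_matches_finite_differences(self, f64, rng, gradcheck,
                                                 scan_oracle):
        inst = _random_scan_instance(rng, L=5, c=2, n=2)
        wts = rng.normal(size=inst[0].shape)
        ts = [nn.Tensor(a.copy()) for a in inst]
        for t in ts:
            t.requires_grad = True
        (selective_scan(*ts) * wts).sum().backward()
        for i, (t, a) in enumerate(zip(ts, inst)):
            def f(arr, i=i):
                args = [arr if j == i else inst[j] for j in range(6)]
                return float((scan_oracle(*args) * wts).sum())
            num = gradcheck(f, a)
            np.testing.assert_allclose(t.grad, num, rtol=2e-4, atol=1e-7)


class TestMambaBlock:
    def test_shape_preserved(self, f64, rng):
        with nn.init_scope(0):
            blk = MambaBlock(4)
        w = rng.normal(size=(1, 10, 4))
        assert blk(nn.Tensor(w)).shape == (1, 10, 4)

    def test_default_hyperparameters(self, f64):
        with nn.init_scope(0):
            blk = MambaBlock(64)
        assert blk.inner == 128 and blk.state_dim == 16 and blk.dt_rank == 4

    def test_zero_gate_branch_leaves_only_output_bias(self, f64, rng):
        with nn.init_scope(0):
            blk = MambaBlock(3)
        blk.gate_proj.weight.data[:] = 0
        blk.gate_proj.bias.data[:] = 0
        w = rng.normal(size=(1, 6, 3))
        out = blk(nn.Tensor(w)).data
        np.testing.assert_allclose(out, np.broadcast_to(blk.out_proj.bias.data,
                                                        out.shape), atol=1e-12)

    def test_non_integer_expansion_rejected(self, f64):
        with pytest.raises(ValueError, match="integer"):
            with nn.init_scope(0):
                MambaBlock(3, expansion=1.5)

    def test_forward_equals_step_by_step_oracle(self, f64, rng, scan_oracle):
        """Direct numpy composition of the five printed steps (linear ->
        causal conv -> SiLU -> scan -> layer norm, gated) vs the module."""
        from scipy.special import expit
        with nn.init_scope(8):
            blk = MambaBlock(2, state_dim=3)
        w = rng.normal(size=(1, 8, 2))

        x = w @ blk.in_proj.weight.data + blk.in_proj.bias.data
        # causal depthwise conv
        k = blk.conv1d.weight.shape[1]
        xp = np.pad(x, ((0, 0), (k - 1, 0), (0, 0)))
        conv = np.zeros_like(x)
        for t in range(k):
            conv += blk.conv1d.weight.data[:, t] * xp[:, t:t + 8, :]
        conv += blk.conv1d.bias.data
        u = conv * expit(conv)                                   # SiLU
        dbc = u @ blk.x_proj.weight.data
        r, n = blk.dt_rank, blk.state_dim
        dt = np.logaddexp(0, dbc[:, :, :r] @ blk.dt_proj.weight.data
                          + blk.dt_proj.bias.data)
        y = scan_oracle(u, dt, -np.exp(blk.A_log.data), dbc[:, :, r:r + n],
                        dbc[:, :, r + n:], blk.D.data)
        mu = y.mean(-1, keepdims=True)
        z1 = (y - mu) / np.sqrt(((y - mu) ** 2).mean(-1, keepdims=True) + 1e-5)
        z1 = z1 * blk.norm.weight.data + blk.norm.bias.data
        g = w @ blk.gate_proj.weight.data + blk.gate_proj.bias.data
        z2 = g * expit(g)
        expect = (z1 * z2) @ blk.out_proj.weight.data + blk.out_proj.bias.data
        np.testing.assert_allclose(blk(nn.Tensor(w)).data, expect, rtol=1e-6,
                                   atol=1e-9)


class TestVAM:
    def test_shape_preserving_at_any_level(self, f64, rng):
        for c, hw in [(4, 8), (8, 4)]:
            with nn.init_scope(0):
                mod = VAM(c).eval()
            x = rng.normal(size=(1, c, hw, hw))
            assert mod(nn.Tensor(x)).shape == x.shape

    def test_zeroed_mamba_branch_reduces_to_local_path(self, f64, rng):
        with nn.init_scope(0):
            mod = VAM(3).eval()
        mod.mamba.out_proj.weight.data[:] = 0
        mod.mamba.out_proj.bias.data[:] = 0
        x = rng.normal(size=(1, 3, 4, 4))
        got = mod(nn.Tensor(x)).data
        zeros = nn.Tensor(np.zeros((1, 3, 4, 4)))
        import lightcf.nn.tensor as T
        fused = mod.fuse(T.concat([zeros, mod.local(nn.Tensor(x))], axis=1))
        expect = mod.sa(mod.ca(fused)).data
        np.testing.assert_allclose(got, expect, rtol=1e-10)

    def test_deterministic(self, f64, rng):
        with nn.init_scope(0):
            mod = VAM(2).eval()
        x = rng.normal(size=(1, 2, 4, 4))
        np.testing.assert_array_equal(mod(nn.Tensor(x)).data, mod(nn.Tensor(x)).data)
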