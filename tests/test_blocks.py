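"""Shared blocks: channel/spatial attention, SE weights, residual and
decoder blocks, each checked against an independent scalar or dense oracle."""
import numpy as np
import pytest
from scipy.special import expit

import lightcf.nn as nn
from lightcf.blocks import (ChannelAttention, DecoderBlock, ResidualBlock,
                            SEWeight, SpatialAttention)
from lightcf.nn import tensor as T


@pytest.fixture
def ca(f64):
    with nn.init_scope(3):
        return ChannelAttention(2, reduction=4)


class TestChannelAttention:
    def test_gate_invariant_to_spatial_shuffling(self, f64, rng):
        """The gate sees only channel means, so rearranging pixels within
        each channel cannot change it (the GAP symmetry)."""
        with nn.init_scope(0):
            mod = ChannelAttention(4)
        x = rng.normal(size=(1, 4, 3, 3))
        perm = rng.permutation(9)
        xs = x.reshape(1, 4, 9)[:, :, perm].reshape(1, 4, 3, 3)
        np.testing.assert_allclose(mod.gate(nn.Tensor(x)).data,
                                   mod.gate(nn.Tensor(xs)).data, rtol=1e-12)

    def test_zero_channel_stays_zero(self, f64, rng):
        with nn.init_scope(0):
            mod = ChannelAttention(3)
        x = rng.normal(size=(1, 3, 4, 4))
        x[:, 1] = 0.0
        assert np.all(mod(nn.Tensor(x)).data[:, 1] == 0)

    def test_gate_equals_scalar_chain_oracle(self, ca):
        # 2-channel 2x2 map with channel means (0, 10) and fixed MLP weights:
        # the gate must equal an independent pool->linear->relu->linear->sigmoid.
        x = np.zeros((1, 2, 2, 2))
        x[0, 1] = 10.0
        w1, b1 = ca.fc1.weight.data, ca.fc1.bias.data
        w2, b2 = ca.fc2.weight.data, ca.fc2.bias.data
        pooled = np.array([0.0, 10.0])
        expect = expit(np.maximum(pooled @ w1 + b1, 0) @ w2 + b2)
        got = ca.gate(nn.Tensor(x)).data[0]
        np.testing.assert_allclose(got, expect, rtol=1e-12)

    def test_gate_strictly_inside_unit_interval(self, f64, rng):
        with nn.init_scope(1):
            mod = ChannelAttention(8)
        g = mod.gate(nn.Tensor(rng.normal(size=(2, 8, 5, 5)))).data
        assert np.all((g > 0) & (g < 1))

    def test_rejects_empty_channels(self):
        with pytest.raises(ValueError):
            ChannelAttention(0)


class TestSpatialAttention:
    def test_constant_input_gives_constant_gate(self, f64, rng):
        with nn.init_scope(0):
            mod = SpatialAttention()
            mod.conv.weight.data = rng.normal(size=mod.conv.weight.shape)
        x = np.full((1, 3, 6, 6), 2.5)
        g = mod.gate(nn.Tensor(x)).data
        # reflect-free zero padding breaks edge symmetry; interior is constant
        inner = g[0, 0, 3:-3, 3:-3]
        assert inner.size == 0 or np.allclose(inner, inner.flat[0])
        out = mod(nn.Tensor(x)).data
        np.testing.assert_allclose(out, x * g, rtol=1e-12)

    def test_zero_conv_gives_half_gate(self, f64, rng):
        with nn.init_scope(0):
            mod = SpatialAttention()  # conv weight zero-initialised, bias zero
        x = rng.normal(size=(2, 4, 5, 5))
        np.testing.assert_allclose(mod(nn.Tensor(x)).data, 0.5 * x, rtol=1e-12)

    def test_gate_matches_dense_conv_oracle(self, f64, rng, conv_oracle):
        with nn.init_scope(0):
            mod = SpatialAttention()
        mod.conv.weight.data = rng.normal(size=mod.conv.weight.shape)
        x = np.zeros((1, 2, 9, 9))
        x[0, 0, 4, 4] = 3.0   # single hot pixel
        stack = np.stack([x[0].mean(axis=0), x[0].max(axis=0)])[None]
        expect = expit(conv_oracle(stack, mod.conv.weight.data,
                                   mod.conv.bias.data, padding=3))
        np.testing.assert_allclose(mod.gate(nn.Tensor(x)).data, expect, rtol=1e-9)


class TestSEWeight:
    def test_logits_invariant_to_spatial_shuffling(self, f64, rng):
        with nn.init_scope(0):
            se = SEWeight(4)
        x = rng.normal(size=(1, 4, 3, 3))
        perm = rng.permutation(9)
        xs = x.reshape(1, 4, 9)[:, :, perm].reshape(1, 4, 3, 3)
        np.testing.assert_allclose(se(nn.Tensor(x)).data,
                                   se(nn.Tensor(xs)).data, rtol=1e-12)

    def test_zero_input_zero_bias_gives_zero_logits(self, f64):
        with nn.init_scope(0):
            se = SEWeight(4)
        se.fc1.bias.data[:] = 0
        se.fc2.bias.data[:] = 0
        assert np.all(se(nn.Tensor(np.zeros((1, 4, 2, 2)))).data == 0)

    def test_logits_equal_hand_computed_chain(self, f64, rng):
        with nn.init_scope(5):
            se = SEWeight(2, reduction=4)
        x = rng.normal(size=(1, 2, 1, 1))
        pooled = x[0, :, 0, 0]
        expect = (np.maximum(pooled @ se.fc1.weight.data + se.fc1.bias.data, 0)
                  @ se.fc2.weight.data + se.fc2.bias.data)
        np.testing.assert_allclose(se(nn.Tensor(x)).data[0], expect, rtol=1e-12)


class TestResidualBlock:
    def test_zeroed_convs_equal_channels_is_identity(self, f64, rng):
        with nn.init_scope(0):
            blk = ResidualBlock(4, 4)
        for p in blk.parameters():
            if p.ndim == 4:
                p.data[:] = 0
        blk.eval()
        x = np.abs(rng.normal(size=(1, 4, 5, 5)))   # positive -> final ReLU inert
        np.testing.assert_allclose(blk(nn.Tensor(x)).data, x, rtol=1e-6)

    def test_shape_contract(self, f64, rng):
        with nn.init_scope(0):
            blk = ResidualBlock(3, 16)
        assert blk(nn.Tensor(rng.normal(size=(1, 3, 8, 8)))).shape == (1, 16, 8, 8)

    def test_gradient_matches_finite_difference(self, f64, rng, gradcheck):
        with nn.init_scope(2):
            blk = ResidualBlock(2, 3)
        blk.eval()
        x = rng.normal(size=(1, 2, 4, 4))
        wts = rng.normal(size=(1, 3, 4, 4))
        t = nn.Tensor(x)
        t.requires_grad = True
        (blk(t) * wts).sum().backward()
        num = gradcheck(lambda a: float((blk(nn.Tensor(a)).data * wts).sum()), x)
        err = np.abs(t.grad - num).max() / (np.abs(num).max() + 1e-12)
        assert err < 1e-4


class TestDecoderBlock:
    def test_shape_contract(self, f64, rng):
        with nn.init_scope(0):
            dec = DecoderBlock(128, 128, 128)
        x = rng.normal(size=(1, 128, 4, 4))
        skip = rng.normal(size=(1, 128, 8, 8))
        assert dec(nn.Tensor(x), nn.Tensor(skip)).shape == (1, 128, 8, 8)

    def test_zero_inputs_give_finite_bias_propagation(self, f64):
        with nn.init_scope(0):
            dec = DecoderBlock(4, 4, 4)
        dec.eval()
        out = dec(nn.Tensor(np.zeros((1, 4, 2, 2))),
                  nn.Tensor(np.zeros((1, 4, 4, 4)))).data
        assert np.all(np.isfinite(out))
        out2 = dec(nn.Tensor(np.zeros((1, 4, 2, 2))),
                   nn.Tensor(np.zeros((1, 4, 4, 4)))).data
        np.testing.assert_array_equal(out, out2)

    def test_mismatched_spatial_ratio_raises(self, f64, rng):
        with nn.init_scope(0):
            dec = DecoderBlock(4, 4, 4)
        with pytest.raises(ValueError, match="twice"):
            dec(nn.Tensor(rng.normal(size=(1, 4, 3, 3))),
                nn.Tensor(rng.normal(size=(1, 4, 7, 7))))


def test_gating_preserves_shape_and_contracts_magnitude(f64, rng):
    """|gated output| <= |input| elementwise for both attention flavours."""
    with nn.init_scope(0):
        ca = ChannelAttention(6)
        sa = SpatialAttention()
    sa.conv.weight.data = rng.normal(size=sa.conv.weight.shape)
    x = rng.normal(size=(2, 6, 8, 8))
    for mod in (ca, sa):
        y = mod(nn.Tensor(x)).data
        assert y.shape == x.shape
        assert np.all(np.abs(y) <= np.abs(x) + 1e-12)
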