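"""Visual attention Mamba skip-connection module.

Encoder features are flattened to a raster-order sequence, passed through
a gated selective-state-space (Mamba) block to model long-range context,
reshaped back, fused with a 1x1-convolution branch that preserves local
detail, and finally recalibrated by channel then spatial attention.

State-space internals follow the standard Mamba parameterisation:
channel expansion 2x, state dimension N = 16, step-size projection rank
ceil(C / 16), a causal depth-wise 1-D convolution of kernel 4, A
initialised to -(1..N) per channel and skip gain D = 1.
"""
from __future__ import annotations

import math

import numpy as np

from . import nn
from .blocks import ChannelAttention, SpatialAttention
from .nn import modules as _mods
from .nn import tensor as T
from .nn.scan import selective_scan


def flatten_to_sequence(x):
    """(B, C, H, W) -> (B, L=H*W, C) in raster order (rows left-to-right)."""
    b, c, h, w = x.shape
    return T.reshape(T.transpose(x, (0, 2, 3, 1)), (b, h * w, c))


def reshape_to_map(w, height: int, width: int):
    """Exact inverse of :func:`flatten_to_sequence`."""
    b, L, c = w.shape
    if L != height * width:
        raise ValueError(f"sequence length {L} != {height}x{width}")
    return T.transpose(T.reshape(w, (b, height, width, c)), (0, 3, 1, 2))


class MambaBlock(nn.Module):
    """Gated selective-scan block over (B, L, C) sequences (shape preserving)."""

    def __init__(self, channels: int, expansion: float = 2.0, state_dim: int = 16,
                 conv_kernel: int = 4, dt_rank: int | None = None,
                 dt_min: float = 1e-3, dt_max: float = 0.1):
        super().__init__()
        inner = expansion * channels
        if abs(inner - round(inner)) > 1e-9:
            raise ValueError(
                f"expansion {expansion} x channels {channels} must be an integer")
        inner = int(round(inner))
        self.channels, self.inner, self.state_dim = channels, inner, state_dim
        self.dt_rank = dt_rank if dt_rank is not None else math.ceil(channels / 16)

        self.in_proj = nn.Linear(channels, inner)
        self.gate_proj = nn.Linear(channels, inner)
        self.conv1d = nn.CausalConv1d(inner, conv_kernel)
        self.x_proj = nn.Linear(inner, self.dt_rank + 2 * state_dim, bias=False)
        self.dt_proj = nn.Linear(self.dt_rank, inner)
        # Step sizes start log-uniform in [dt_min, dt_max] via the softplus bias.
        dt = np.exp(_mods._INIT_RNG.uniform(np.log(dt_min), np.log(dt_max), inner))
        self.dt_proj.bias.data = np.log(np.expm1(dt)).astype(self.dt_proj.bias.dtype)
        self.A_log = nn.Parameter(np.tile(np.log(np.arange(1, state_dim + 1)), (inner, 1)))
        self.D = nn.Parameter(np.ones(inner))
        self.norm = nn.LayerNorm(inner)
        self.out_proj = nn.Linear(inner, channels)

    def ssm(self, u):
        """Selective scan with input-dependent (dt, B, C)."""
        n, r = self.state_dim, self.dt_rank
        dbc = self.x_proj(u)
        dt = T.softplus(self.dt_proj(dbc[:, :, :r]))
        B = dbc[:, :, r:r + n]
        C = dbc[:, :, r + n:]
        A = -T.exp(self.A_log)
        return selective_scan(u, dt, A, B, C, self.D)

    def forward(self, w):
        z1 = self.norm(self.ssm(T.silu(self.conv1d(self.in_proj(w)))))
        z2 = T.silu(self.gate_proj(w))
        return self.out_proj(z1 * z2)


class VAM(nn.Module):
    """Mamba-based long-range skip module; shape preserving at any level."""

    def __init__(self, channels: int, expansion: float = 2.0, state_dim: int = 16,
                 conv_kernel: int = 4, dt_rank: int | None = None,
                 ca_reduction: int = 4):
        super().__init__()
        self.ln = nn.LayerNorm(channels)
        self.mamba = MambaBlock(channels, expansion, state_dim, conv_kernel, dt_rank)
        self.local = nn.Conv2d(channels, channels, 1)
        self.fuse = nn.Conv2d(2 * channels, channels, 1)
        self.ca = ChannelAttention(channels, ca_reduction)
        self.sa = SpatialAttention()

    def forward(self, x):
        b, c, h, w = x.shape
        seq = self.mamba(self.ln(flatten_to_sequence(x)))
        wout = reshape_to_map(seq, h, w)
        x2 = self.local(x)
        fused = self.fuse(T.concat([wout, x2], axis=1))
        return self.sa(self.ca(fused))
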