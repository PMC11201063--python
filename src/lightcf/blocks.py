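"""Shared building blocks: residual conv block, channel/spatial attention,
squeeze-excitation weights and the decoder block.

All blocks consume and produce (batch, channel, height, width) feature maps.
Attention gates are produced by a sigmoid and therefore lie strictly in
(0, 1); gating never changes the shape of its input.
"""
from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T


class ChannelAttention(nn.Module):
    """Squeeze-and-excitation channel gate.

    Global average pooling followed by a two-layer bottleneck MLP and a
    sigmoid; the input is rescaled per channel. The bottleneck width is
    ``max(channels // reduction, min_width)`` so narrow stages (16 channels)
    keep a non-degenerate hidden layer.
    """

    def __init__(self, channels: int, reduction: int = 4, min_width: int = 4):
        super().__init__()
        if channels < 1:
            raise ValueError("channel_attention needs at least one channel")
        hidden = max(channels // reduction, min_width)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def gate(self, x):
        pooled = nn.global_avg_pool(x)                      # (B, C)
        return T.sigmoid(self.fc2(T.relu(self.fc1(pooled))))

    def forward(self, x):
        g = self.gate(x)
        return x * g.reshape(g.shape[0], g.shape[1], 1, 1)


class SpatialAttention(nn.Module):
    """Spatial gate from stacked per-pixel channel mean and max (7x7 conv)."""

    def __init__(self, kernel_size: int = 7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel_size, bias=True)
        # A zero-initialised conv keeps the initial gate at a neutral 0.5.
        self.conv.weight.data = np.zeros_like(self.conv.weight.data)

    def gate(self, x):
        avg = x.mean(axis=1, keepdims=True)
        mx = T.max_(x, axis=1, keepdims=True)
        return T.sigmoid(self.conv(T.concat([avg, mx], axis=1)))

    def forward(self, x):
        return x * self.gate(x)


class SEWeight(nn.Module):
    """Per-channel squeeze-excitation logits (no squashing).

    Used by the pyramid split attention bottleneck, where the branch
    logits are normalised jointly by a softmax across branches.
    """

    def __init__(self, channels: int, reduction: int = 4, min_width: int = 4):
        super().__init__()
        hidden = max(channels // reduction, min_width)
        self.fc1 = nn.Linear(channels, hidden)
        self.fc2 = nn.Linear(hidden, channels)

    def forward(self, x):
        return self.fc2(T.relu(self.fc1(nn.global_avg_pool(x))))


class ResidualBlock(nn.Module):
    """Two 3x3 conv-BN-ReLU layers with an identity or 1x1-projected skip."""

    def __init__(self, cin: int, cout: int):
        super().__init__()
        self.conv1 = nn.Conv2d(cin, cout, 3, bias=False)
        self.bn1 = nn.BatchNorm2d(cout)
        self.conv2 = nn.Conv2d(cout, cout, 3, bias=False)
        self.bn2 = nn.BatchNorm2d(cout)
        if cin != cout:
            self.proj = nn.Sequential(nn.Conv2d(cin, cout, 1, bias=False),
                                      nn.BatchNorm2d(cout))
        else:
            self.proj = nn.Identity()

    def forward(self, x):
        y = T.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        return T.relu(y + self.proj(x))


class DecoderBlock(nn.Module):
    """Bilinear 2x upsample, concatenate the skip, then a residual double conv."""

    def __init__(self, cin_x: int, cin_skip: int, cout: int):
        super().__init__()
        self.up = nn.UpsampleBilinear2x()
        self.body = ResidualBlock(cin_x + cin_skip, cout)

    def forward(self, x, skip):
        xb, _, xh, xw = x.shape
        sb, _, sh, sw = skip.shape
        if xb != sb or sh != 2 * xh or sw != 2 * xw:
            raise ValueError(
                f"skip spatial size {sh}x{sw} must be exactly twice the input "
                f"{xh}x{xw} (same batch)")
        return self.body(T.concat([self.up(x), skip], axis=1))
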