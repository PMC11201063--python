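"""Fusion attention encoder stage.

Large Kernel Attention (LKA) decomposes a large-receptive-field
convolution into a 5x5 depth-wise convolution, a 7x7 depth-wise
convolution with dilation 3 and a pointwise 1x1 convolution; the result
is used as a multiplicative attention map over the input, giving a
21 x 21 effective receptive field at depth-wise cost.

The encoder stage first lifts the input with a 3x3 convolution, then
fuses an LKA branch (1x1 -> GELU -> LKA -> 1x1) with a plain 1x1 branch
by addition, mixes with a 3x3 convolution and finally recalibrates
channels with a squeeze-excitation gate.
"""
from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .blocks import ChannelAttention
from .nn import tensor as T


@dataclass(frozen=True)
class LKAConfig:
    dw_kernel: int = 5
    dwd_kernel: int = 7
    dwd_dilation: int = 3

    def __post_init__(self):
        if self.dw_kernel % 2 == 0 or self.dwd_kernel % 2 == 0:
            raise ValueError("LKA kernel sizes must be odd")
        if self.dwd_dilation < 1:
            raise ValueError("dilation must be a positive integer")

    @property
    def receptive_field(self) -> int:
        return self.dw_kernel + (self.dwd_kernel - 1) * self.dwd_dilation


class LKA(nn.Module):
    """attention = 1x1(DW-D-Conv(DW-Conv(x))); output = attention * x."""

    def __init__(self, channels: int, cfg: LKAConfig = LKAConfig()):
        super().__init__()
        self.cfg = cfg
        self.dw = nn.Conv2d(channels, channels, cfg.dw_kernel, groups=channels)
        self.dwd = nn.Conv2d(channels, channels, cfg.dwd_kernel,
                             dilation=cfg.dwd_dilation, groups=channels)
        self.pw = nn.Conv2d(channels, channels, 1)

    def attention(self, x):
        return self.pw(self.dwd(self.dw(x)))

    def forward(self, x):
        return self.attention(x) * x


class FAEncoder(nn.Module):
    """One fusion-attention encoder stage (stride 1; pooling lives outside)."""

    def __init__(self, cin: int, cout: int, lka_cfg: LKAConfig = LKAConfig(),
                 with_ca: bool = True, ca_reduction: int = 4):
        super().__init__()
        self.conv_in = nn.Conv2d(cin, cout, 3, bias=False)
        self.bn_in = nn.BatchNorm2d(cout)
        self.branch_pre = nn.Conv2d(cout, cout, 1)
        self.lka = LKA(cout, lka_cfg)
        self.branch_post = nn.Conv2d(cout, cout, 1)
        self.branch_plain = nn.Conv2d(cout, cout, 1)
        self.fuse = nn.Conv2d(cout, cout, 3, bias=False)
        self.bn_fuse = nn.BatchNorm2d(cout)
        self.ca = ChannelAttention(cout, ca_reduction) if with_ca else nn.Identity()

    def forward(self, x):
        x2 = T.relu(self.bn_in(self.conv_in(x)))
        y1 = self.branch_post(self.lka(T.gelu(self.branch_pre(x2))))
        y2 = self.branch_plain(x2)
        out = T.relu(self.bn_fuse(self.fuse(y1 + y2)))
        return self.ca(out)
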