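"""Pyramid split attention bottleneck.

The bottleneck feature map is processed by S parallel group convolutions
with pyramid kernel sizes K_i = 2*(i+1)+1 (3, 5, 7, 9 for S = 4), each
emitting C/S channels. Per-branch squeeze-excitation logits are
normalised by a softmax *across branches* (independently per channel
slot), the branch maps are rescaled by their attention weights and
concatenated back to C channels.

Two branch-input conventions are supported:

* ``"full"`` (default): every branch convolves the full C-channel input,
  as in the reference pyramid-split-attention implementation. This is the
  convention under which the network's parameter budget matches the
  published ablation table.
* ``"split"``: the input is first split into S chunks of C/S channels and
  branch i convolves only chunk i (the textual description of the
  module).
"""
from __future__ import annotations

from dataclasses import dataclass

from . import nn
from .blocks import SEWeight
from .nn import tensor as T


def pyramid_kernel(i: int) -> int:
    return 2 * (i + 1) + 1


def pyramid_groups(i: int) -> int:
    return 2 ** ((pyramid_kernel(i) - 1) // 2)


@dataclass(frozen=True)
class PSAConfig:
    splits: int = 4
    branch_input: str = "full"           # "full" | "split"
    groups: tuple = ()                    # override; default from formula/reference
    se_reduction: int = 4

    def __post_init__(self):
        if self.splits < 1:
            raise ValueError("splits must be a positive integer")
        if self.branch_input not in ("full", "split"):
            raise ValueError(f"unknown branch_input {self.branch_input!r}")
        if self.groups and len(self.groups) != self.splits:
            raise ValueError("groups override must have one entry per split")

    def kernel_sizes(self):
        return [pyramid_kernel(i) for i in range(self.splits)]

    def group_sizes(self):
        if self.groups:
            return list(self.groups)
        if self.branch_input == "full":
            # Reference convention: the 3x3 branch is ungrouped.
            return [1] + [pyramid_groups(i) for i in range(1, self.splits)]
        return [pyramid_groups(i) for i in range(self.splits)]


class PSA(nn.Module):
    def __init__(self, channels: int, cfg: PSAConfig = PSAConfig()):
        super().__init__()
        s = cfg.splits
        if channels % s:
            raise ValueError(f"channels {channels} not divisible by splits {s}")
        self.cfg, self.channels = cfg, channels
        cs = channels // s
        cin = channels if cfg.branch_input == "full" else cs
        self.branches = nn.ModuleList([
            nn.Conv2d(cin, cs, k, groups=g)
            for k, g in zip(cfg.kernel_sizes(), cfg.group_sizes())
        ])
        self.se = nn.ModuleList([SEWeight(cs, cfg.se_reduction) for _ in range(s)])

    def split_conv(self, x):
        """The S multi-scale branch maps F_i, each with C/S channels."""
        s = self.cfg.splits
        cs = self.channels // s
        if self.cfg.branch_input == "full":
            return [conv(x) for conv in self.branches]
        chunks = [x[:, i * cs:(i + 1) * cs] for i in range(s)]
        return [conv(c) for conv, c in zip(self.branches, chunks)]

    def branch_attention(self, feats):
        """Softmax-across-branches weights; sums to 1 per channel slot."""
        logits = T.concat([T.reshape(se(f), (f.shape[0], 1, -1))
                           for se, f in zip(self.se, feats)], axis=1)  # (B, S, C/S)
        return T.softmax(logits, axis=1)

    def forward(self, x):
        feats = self.split_conv(x)
        att = self.branch_attention(feats)
        outs = []
        for i, f in enumerate(feats):
            w = att[:, i]
            outs.append(f * T.reshape(w, (w.shape[0], -1, 1, 1)))
        return T.concat(outs, axis=1)
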