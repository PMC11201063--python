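"""LightCF-Net assembly: encoder-decoder with five stages, optional fusion
attention encoder stages, Mamba skip modules and a pyramid split attention
bottleneck, plus the ablation variants used to isolate each contribution.

Stage channels default to (16, 32, 64, 128, 128); a 2x2 max-pool precedes
stages 2-5, so the bottleneck sits at 1/16 resolution and inputs must have
spatial sizes divisible by 16. The decoder mirrors with four bilinear
upsample blocks and ends in a 1x1 convolution with a sigmoid, producing a
single foreground-probability channel.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .blocks import DecoderBlock, ResidualBlock
from .faencoder import FAEncoder, LKAConfig
from .nn import tensor as T
from .psa import PSA, PSAConfig
from .vam import VAM

VARIANTS = ("baseline", "faencoder_no_ca", "faencoder", "vam", "faencoder_vam", "full")

DOWNSAMPLE_FACTOR = 16


@dataclass
class ModelConfig:
    variant: str = "full"
    stage_channels: tuple = (16, 32, 64, 128, 128)
    decoder_channels: tuple = (64, 64, 32, 16)
    ca_reduction: int = 4
    lka: LKAConfig = field(default_factory=LKAConfig)
    vam_expansion: float = 2.0
    vam_state_dim: int = 16
    vam_conv_kernel: int = 4
    vam_dt_rank: int | None = None       # None -> ceil(C / 16) per level
    vam_levels: tuple = (0, 1, 2, 3)
    psa: PSAConfig = field(default_factory=PSAConfig)
    out_channels: int = 1

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if len(self.stage_channels) != 5 or len(self.decoder_channels) != 4:
            raise ValueError("expect 5 encoder stage widths and 4 decoder widths")

    @property
    def use_faencoder(self) -> bool:
        return self.variant in ("faencoder_no_ca", "faencoder", "faencoder_vam", "full")

    @property
    def use_ca(self) -> bool:
        return self.variant != "faencoder_no_ca"

    @property
    def use_vam(self) -> bool:
        return self.variant in ("vam", "faencoder_vam", "full")

    @property
    def use_psa(self) -> bool:
        return self.variant == "full"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_channels"] = list(self.stage_channels)
        d["decoder_channels"] = list(self.decoder_channels)
        d["vam_levels"] = list(self.vam_levels)
        d["lka"] = dataclasses.asdict(self.lka)
        d["psa"] = dataclasses.asdict(self.psa)
        d["psa"]["groups"] = list(self.psa.groups)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "lka" in d and isinstance(d["lka"], dict):
            d["lka"] = LKAConfig(**d["lka"])
        if "psa" in d and isinstance(d["psa"], dict):
            p = dict(d["psa"])
            p["groups"] = tuple(p.get("groups", ()))
            d["psa"] = PSAConfig(**p)
        for key in ("stage_channels", "decoder_channels", "vam_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc.get("model", doc))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"model": self.to_dict()}, fh, sort_keys=False)


class LightCFNet(nn.Module):
    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        ch = cfg.stage_channels

        def encoder_stage(cin, cout):
            if cfg.use_faencoder:
                return FAEncoder(cin, cout, cfg.lka, with_ca=cfg.use_ca,
                                 ca_reduction=cfg.ca_reduction)
            return ResidualBlock(cin, cout)

        self.stage1 = ResidualBlock(3, ch[0])
        self.pool = nn.MaxPool2d()
        self.stage2 = encoder_stage(ch[0], ch[1])
        self.stage3 = encoder_stage(ch[1], ch[2])
        self.stage4 = encoder_stage(ch[2], ch[3])
        self.stage5 = encoder_stage(ch[3], ch[4])

        if cfg.use_vam:
            skips = {}
            for lvl in cfg.vam_levels:
                skips[str(lvl)] = VAM(ch[lvl], cfg.vam_expansion, cfg.vam_state_dim,
                                      cfg.vam_conv_kernel, cfg.vam_dt_rank,
                                      cfg.ca_reduction)
            self.skip_mods = nn.ModuleList([
                skips.get(str(lvl), nn.Identity()) for lvl in range(4)])
        else:
            self.skip_mods = nn.ModuleList([nn.Identity() for _ in range(4)])

        self.bottleneck = PSA(ch[4], cfg.psa) if cfg.use_psa else nn.Identity()

        dc = cfg.decoder_channels
        self.dec4 = DecoderBlock(ch[4], ch[3], dc[0])
        self.dec3 = DecoderBlock(dc[0], ch[2], dc[1])
        self.dec2 = DecoderBlock(dc[1], ch[1], dc[2])
        self.dec1 = DecoderBlock(dc[2], ch[0], dc[3])
        self.head = nn.Conv2d(dc[3], cfg.out_channels, 1)

    def forward(self, x):
        b, c, h, w = x.shape
        if c != 3:
            raise ValueError(f"expected 3 input channels, got {c}")
        if h % DOWNSAMPLE_FACTOR or w % DOWNSAMPLE_FACTOR:
            raise ValueError(
                f"spatial size {h}x{w} must be divisible by {DOWNSAMPLE_FACTOR}")
        s1 = self.stage1(x)
        s2 = self.stage2(self.pool(s1))
        s3 = self.stage3(self.pool(s2))
        s4 = self.stage4(self.pool(s3))
        s5 = self.stage5(self.pool(s4))
        z = self.bottleneck(s5)
        skips = [m(s) for m, s in zip(self.skip_mods, (s1, s2, s3, s4))]
        d = self.dec4(z, skips[3])
        d = self.dec3(d, skips[2])
        d = self.dec2(d, skips[1])
        d = self.dec1(d, skips[0])
        return T.sigmoid(self.head(d))


def build_model(cfg: ModelConfig, seed: int = 0) -> LightCFNet:
    """Construct a network with deterministic, seeded initial weights."""
    with nn.init_scope(seed):
        return LightCFNet(cfg)


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalars."""
    return model.num_parameters()


def model_forward(model: LightCFNet, images) -> np.ndarray:
    """Deterministic eval-mode forward; returns probabilities in (0, 1)."""
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            out = model(nn.as_tensor(np.asarray(images, dtype=T.default_dtype())))
    finally:
        model.train(was_training)
    return out.data
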