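"""Seeded synthetic colonoscopy-like fixtures.

The generator emulates the qualitative challenge axes of endoscopic polyp
images — polyps of varying size, shape and colour, low contrast against
the surrounding mucosa, uneven illumination and specular highlights —
without claiming visual realism. Backgrounds are multi-octave value
noise tinted mucosa-pink under a smooth illumination gradient; polyps
are ellipses whose boundaries are perturbed by random radial harmonics;
the mask is the exact polyp support, so segmentation labels are
noise-free by construction.

Every sample is a pure function of (config, index): the stream is fully
reproducible and any sample can be generated in isolation.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

MUCOSA_RGB = np.array([196.0, 120.0, 108.0])      # pale pink mucosa base
POLYP_TINT = np.array([1.0, -0.35, -0.45])        # direction of polyp colour shift


@dataclass(frozen=True)
class SynthConfig:
    image_size: int = 256
    n_polyps: tuple = (1, 3)
    radius_frac: tuple = (0.06, 0.22)              # of image size
    boundary_harmonics: int = 4                    # radial cosine harmonics 2..k+1
    harmonic_amplitude: float = 0.22               # total relative perturbation
    contrast_delta: float = 0.25                   # polyp tint strength (0 = invisible)
    illumination_strength: float = 0.35            # relative vignette/gradient depth
    specular_count: tuple = (2, 6)
    noise_sigma: float = 0.02                      # sensor noise (fraction of 255)
    texture_strength: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.radius_frac[0] <= self.radius_frac[1]):
            raise ValueError("radius_frac range must be positive and ordered")
        if self.radius_frac[1] * (1 + self.harmonic_amplitude) > 0.5:
            raise ValueError("polyp radius range exceeds the image half-size")
        if self.n_polyps[0] < 1 or self.n_polyps[0] > self.n_polyps[1]:
            raise ValueError("n_polyps range is degenerate")


@dataclass
class SamplePair:
    image: np.ndarray                              # (H, W, 3) uint8
    mask: np.ndarray                               # (H, W) uint8 in {0, 1}
    id: str = ""

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError("image and mask sizes differ")
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask must be binary {0, 1}")


def _value_noise(rng: np.random.Generator, size: int, octaves=(4, 8, 16, 32)) -> np.ndarray:
    """Multi-octave smooth noise in [-1, 1]."""
    out = np.zeros((size, size))
    amp = 1.0
    total = 0.0
    for cells in octaves:
        grid = rng.standard_normal((cells, cells))
        out += amp * ndimage.zoom(grid, size / cells, order=3, mode="reflect",
                                  grid_mode=True)
        total += amp
        amp *= 0.55
    out /= total
    return out / (np.abs(out).max() + 1e-9)


def _polyp_mask(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """One radial-harmonic-perturbed ellipse; returns a boolean mask."""
    n = cfg.image_size
    r0 = rng.uniform(*cfg.radius_frac) * n
    margin = r0 * (1 + cfg.harmonic_amplitude)
    cy = rng.uniform(margin, n - margin)
    cx = rng.uniform(margin, n - margin)
    aspect = rng.uniform(0.6, 1.0)
    tilt = rng.uniform(0, np.pi)
    k = cfg.boundary_harmonics
    amps = rng.uniform(0, 1, k)
    amps *= cfg.harmonic_amplitude / (amps.sum() + 1e-9)
    phases = rng.uniform(0, 2 * np.pi, k)

    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(tilt), np.sin(tilt)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    rad = np.hypot(u, v)
    theta = np.arctan2(v, u)
    rim = r0 * (1 + sum(a * np.cos((i + 2) * theta + p)
                        for i, (a, p) in enumerate(zip(amps, phases))))
    return rad <= rim


def generate_sample(cfg: SynthConfig, index: int) -> SamplePair:
    """Deterministically generate the `index`-th sample of the stream."""
    rng = np.random.default_rng([cfg.seed, index])
    n = cfg.image_size

    base = MUCOSA_RGB[None, None, :] * (
        1.0 + cfg.texture_strength * _value_noise(rng, n)[:, :, None])

    # Smooth illumination: a directional gradient plus an off-centre vignette.
    yy, xx = np.mgrid[0:n, 0:n] / max(n - 1, 1)
    ang = rng.uniform(0, 2 * np.pi)
    grad = (np.cos(ang) * (xx - 0.5) + np.sin(ang) * (yy - 0.5))
    cy0, cx0 = rng.uniform(0.25, 0.75, 2)
    vig = np.hypot(yy - cy0, xx - cx0)
    illum = 1.0 - cfg.illumination_strength * (0.6 * vig / vig.max() + 0.4 * (grad + 0.5))
    img = base * illum[:, :, None]

    # Polyps: tinted, slightly re-textured regions; union mask is exact.
    mask = np.zeros((n, n), dtype=bool)
    for _ in range(rng.integers(cfg.n_polyps[0], cfg.n_polyps[1] + 1)):
        pm = _polyp_mask(rng, cfg)
        mask |= pm
        sign = rng.choice([-1.0, 1.0])
        tex = _value_noise(rng, n)
        tint = (sign * cfg.contrast_delta * POLYP_TINT[None, None, :]
                * (1.0 + 0.3 * tex[:, :, None]))
        img = np.where(pm[:, :, None], img * (1.0 + tint), img)

    # Specular highlights: small bright elliptical spots (glare).
    n_spec = rng.integers(cfg.specular_count[0], cfg.specular_count[1] + 1)
    for _ in range(n_spec):
        sy, sx = rng.uniform(0, n, 2)
        sr = rng.uniform(0.004, 0.015) * n
        dist2 = ((np.mgrid[0:n][:, None] - sy) ** 2
                 + (np.mgrid[0:n][None, :] - sx) ** 2)
        spot = np.exp(-dist2 / (2 * sr * sr))
        img = img + 255.0 * 0.9 * spot[:, :, None]

    img += 255.0 * cfg.noise_sigma * rng.standard_normal((n, n, 3))
    img = np.clip(img, 0, 255).astype(np.uint8)
    return SamplePair(image=img, mask=mask.astype(np.uint8), id=f"synth_{index:05d}")


def generate_dataset(cfg: SynthConfig, n: int) -> list[SamplePair]:
    return [generate_sample(cfg, i) for i in range(n)]


def materialize(cfg: SynthConfig, n: int, out_dir) -> Path:
    """Write n samples in the standard folder layout (images/ + masks/)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i in range(n):
        s = generate_sample(cfg, i)
        Image.fromarray(s.image).save(out / "images" / f"{s.id}.png")
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            out / "masks" / f"{s.id}.png")
    return out
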