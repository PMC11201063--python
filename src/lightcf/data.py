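"""Dataset I/O, preprocessing and augmentation.

Folder layout follows the common polyp-benchmark convention: an
``images/`` directory of RGB PNG/JPEG frames and a ``masks/`` directory
of binary PNG masks sharing basenames. Masks are binarised at 127.

The training resize protocol resizes frames to 320x320 and takes a
seeded random 256x256 crop; validation/test frames are resized to a
per-dataset evaluation size. Images use bilinear interpolation, masks
nearest-neighbour (labels never bleed).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .synth import SamplePair

IMAGE_EXTS = (".png", ".jpg", ".jpeg")
TRAIN_RESIZE = (320, 320)
TRAIN_CROP = (256, 256)
EVAL_SIZES = {  # per-dataset evaluation sizes (height, width)
    "kvasir": (320, 320),
    "etis": (320, 320),
    "clinicdb": (288, 384),
    "bkai": (480, 480),
}


def _to_binary(mask_arr: np.ndarray) -> np.ndarray:
    return (mask_arr > 127).astype(np.uint8)


def load_pairs(image_dir, mask_dir):
    """Yield co-registered image/mask pairs, sorted by basename."""
    image_dir, mask_dir = Path(image_dir), Path(mask_dir)
    masks = {p.stem: p for p in mask_dir.iterdir()
             if p.suffix.lower() in IMAGE_EXTS}
    images = sorted(p for p in image_dir.iterdir()
                    if p.suffix.lower() in IMAGE_EXTS)
    if not images:
        raise FileNotFoundError(f"no images found under {image_dir}")
    for ipath in images:
        mpath = masks.get(ipath.stem)
        if mpath is None:
            raise FileNotFoundError(f"no mask for image {ipath.name} in {mask_dir}")
        try:
            img = np.asarray(Image.open(ipath).convert("RGB"))
            msk = _to_binary(np.asarray(Image.open(mpath).convert("L")))
        except OSError as exc:
            raise OSError(f"unreadable file: {exc}") from exc
        yield SamplePair(image=img, mask=msk, id=ipath.stem)


def resize_pair(s: SamplePair, size: tuple[int, int]) -> SamplePair:
    """Resize to (height, width); bilinear image, nearest mask."""
    h, w = size
    img = np.asarray(Image.fromarray(s.image).resize((w, h), Image.BILINEAR))
    msk = np.asarray(Image.fromarray(s.mask * 255).resize((w, h), Image.NEAREST))
    return SamplePair(image=img, mask=_to_binary(msk), id=s.id)


def random_crop(s: SamplePair, size: tuple[int, int],
                rng: np.random.Generator) -> SamplePair:
    h, w = size
    H, W = s.mask.shape
    if H < h or W < w:
        raise ValueError(f"crop {h}x{w} larger than image {H}x{W}")
    top = int(rng.integers(0, H - h + 1))
    left = int(rng.integers(0, W - w + 1))
    return SamplePair(image=s.image[top:top + h, left:left + w],
                      mask=s.mask[top:top + h, left:left + w], id=s.id)


def resize_protocol(s: SamplePair, split: str, rng: np.random.Generator | None = None,
                    eval_size: tuple[int, int] = (320, 320)) -> SamplePair:
    """Training: resize 320x320 then seeded random crop 256x256; else resize."""
    if split == "train":
        if rng is None:
            raise ValueError("training resize needs a random generator for the crop")
        return random_crop(resize_pair(s, TRAIN_RESIZE), TRAIN_CROP, rng)
    return resize_pair(s, eval_size)


def augment(s: SamplePair, rng: np.random.Generator) -> SamplePair:
    """Random horizontal/vertical flips and a rotation in [-90, 90] degrees.

    The identical geometric transform is applied to image and mask; the
    mask uses nearest-neighbour interpolation and stays strictly binary.
    """
    img, msk = s.image, s.mask
    if rng.random() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.random() < 0.5:
        img, msk = img[::-1, :], msk[::-1, :]
    angle = float(rng.uniform(-90.0, 90.0))
    img = ndimage.rotate(img, angle, axes=(1, 0), reshape=False, order=1,
                         mode="reflect")
    msk = ndimage.rotate(msk, angle, axes=(1, 0), reshape=False, order=0,
                         mode="constant", cval=0)
    return SamplePair(image=np.ascontiguousarray(img.astype(np.uint8)),
                      mask=np.ascontiguousarray((msk > 0).astype(np.uint8)),
                      id=s.id)


def split_dataset(n: int, seed: int, ratios=(0.8, 0.1, 0.1)):
    """Disjoint, exhaustive train/val/test index split by seeded shuffle."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("split ratios must sum to 1")
    perm = np.random.default_rng(seed).permutation(n)
    n_train = int(round(ratios[0] * n))
    n_val = int(round(ratios[1] * n))
    return (perm[:n_train].tolist(), perm[n_train:n_train + n_val].tolist(),
            perm[n_train + n_val:].tolist())


def to_batch(pairs: list[SamplePair], dtype=np.float32):
    """Stack pairs into (B, 3, H, W) images in [0, 1] and (B, 1, H, W) masks."""
    imgs = np.stack([p.image for p in pairs]).astype(dtype) / 255.0
    msks = np.stack([p.mask for p in pairs]).astype(dtype)[:, None]
    return imgs.transpose(0, 3, 1, 2), msks
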