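"""Training, evaluation and prediction pipeline.

Follows the published protocol: Adam (weight decay 1e-5), batch size 8,
poly learning-rate decay lr = init_lr * (1 - epoch/max_epoch)^power with
init_lr = 1e-3 and power = 0.9, BCE-Dice loss, flip/rotation
augmentation. Everything is seeded: two runs with the same seed, configs
and data produce identical loss curves.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .data import augment, to_batch
from .losses import bce_dice_loss
from .metrics import evaluate_images
from .network import LightCFNet, ModelConfig, build_model
from .synth import SamplePair


def poly_lr(init_lr: float, epoch: int, max_epoch: int, power: float = 0.9) -> float:
    """lr = init_lr * (1 - epoch / max_epoch) ** power; zero at the last epoch."""
    if not 0 <= epoch <= max_epoch:
        raise ValueError(f"epoch {epoch} outside [0, {max_epoch}]")
    return init_lr * (1.0 - epoch / max_epoch) ** power


@dataclass
class TrainConfig:
    init_lr: float = 1e-3
    power: float = 0.9
    max_epoch: int = 200
    batch_size: int = 8
    weight_decay: float = 1e-5
    seed: int = 0
    augment: bool = True
    dice_smooth: float = 1.0
    bce_reduction: str = "mean"
    max_steps: int | None = None           # optional hard cap on optimiser steps
    val_every: int = 1

    def __post_init__(self):
        if self.init_lr <= 0 or self.power <= 0 or self.max_epoch < 1:
            raise ValueError("init_lr, power must be > 0 and max_epoch >= 1")

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(**doc.get("train", doc))


@dataclass
class TrainResult:
    history: list          # one dict per epoch: loss, lr, optional val metrics
    best_state: dict       # weights at the best validation DSC (or last epoch)
    best_epoch: int
    best_val_dsc: float
    steps: int


def _forward_batch(model, pairs, cfg: TrainConfig):
    imgs, msks = to_batch(pairs)
    pred = model(nn.Tensor(imgs))
    return pred, bce_dice_loss(pred, nn.Tensor(msks), smooth=cfg.dice_smooth,
                               bce_reduction=cfg.bce_reduction)


def predict(model: LightCFNet, images: np.ndarray) -> np.ndarray:
    """Eval-mode probability maps for (B, 3, H, W) images in [0, 1]."""
    was_training = model.training
    model.eval()
    try:
        with nn.no_grad():
            out = model(nn.Tensor(np.asarray(images, dtype=np.float32)))
    finally:
        model.train(was_training)
    return out.data


def predict_pairs(model: LightCFNet, pairs: list[SamplePair]) -> list[np.ndarray]:
    imgs, _ = to_batch(pairs)
    return [p[0] for p in predict(model, imgs)]


def evaluate(model: LightCFNet, pairs: list[SamplePair],
             threshold: float = 0.5):
    """Deterministic evaluation; returns (per-image reports, aggregate)."""
    probs = predict_pairs(model, pairs)
    gts = [p.mask for p in pairs]
    return evaluate_images(probs, gts, threshold)


def train(model: LightCFNet, train_pairs: list[SamplePair],
          train_cfg: TrainConfig, val_pairs: list[SamplePair] | None = None,
          log_path=None) -> TrainResult:
    if not train_pairs:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(train_cfg.seed)
    opt = nn.Adam(model.parameters(), lr=train_cfg.init_lr,
                  weight_decay=train_cfg.weight_decay)
    n = len(train_pairs)
    steps_per_epoch = max(1, int(np.ceil(n / train_cfg.batch_size)))
    history = []
    best = dict(state=None, epoch=-1, dsc=-1.0)
    log_fh = open(log_path, "w") if log_path else None
    steps = 0
    try:
        for epoch in range(train_cfg.max_epoch):
            lr = poly_lr(train_cfg.init_lr, epoch, train_cfg.max_epoch,
                         train_cfg.power)
            opt.lr = lr
            model.train()
            order = rng.permutation(n)
            losses = []
            for b in range(steps_per_epoch):
                idx = order[b * train_cfg.batch_size:(b + 1) * train_cfg.batch_size]
                batch = [train_pairs[i] for i in idx]
                if train_cfg.augment:
                    batch = [augment(s, rng) for s in batch]
                _, loss = _forward_batch(model, batch, train_cfg)
                val = loss.item()
                if not np.isfinite(val):
                    raise RuntimeError(
                        f"non-finite loss {val} at epoch {epoch} step {b}: "
                        "try a lower learning rate or check the input data")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(val)
                steps += 1
                if train_cfg.max_steps and steps >= train_cfg.max_steps:
                    break
            rec = {"epoch": epoch, "lr": lr, "loss": float(np.mean(losses)),
                   "steps": steps}
            if val_pairs and (epoch % train_cfg.val_every == 0
                              or epoch == train_cfg.max_epoch - 1):
                _, agg = evaluate(model, val_pairs)
                rec["val_iou"], rec["val_dsc"] = agg.iou, agg.dsc
                if agg.dsc > best["dsc"]:
                    best = dict(state=model.state_dict(), epoch=epoch, dsc=agg.dsc)
            history.append(rec)
            if log_fh:
                log_fh.write(json.dumps(rec) + "\n")
                log_fh.flush()
            if train_cfg.max_steps and steps >= train_cfg.max_steps:
                break
    finally:
        if log_fh:
            log_fh.close()
    if best["state"] is None:
        best = dict(state=model.state_dict(), epoch=len(history) - 1, dsc=float("nan"))
    return TrainResult(history=history, best_state=best["state"],
                       best_epoch=best["epoch"], best_val_dsc=best["dsc"],
                       steps=steps)


# -- checkpoints ------------------------------------------------------------
def save_checkpoint(path, model: LightCFNet, state: dict | None = None) -> None:
    """Weight archive (.npz) plus the YAML model config that built it."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **(state or model.state_dict()))
    model.cfg.to_yaml(path.with_suffix(".yaml"))


def load_checkpoint(path, seed: int = 0) -> LightCFNet:
    path = Path(path)
    cfg = ModelConfig.from_yaml(path.with_suffix(".yaml"))
    model = build_model(cfg, seed=seed)
    with np.load(path) as npz:
        try:
            model.load_state_dict({k: npz[k] for k in npz.files})
        except (KeyError, ValueError) as exc:
            raise ValueError(
                f"checkpoint {path.name} does not match its config: {exc}") from exc
    return model.eval()
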