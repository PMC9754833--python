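"""Optimization loop: Adam with per-update exponential learning-rate decay.

The schedule follows the published recipe — initial learning rate 2e-4,
multiplied by 0.999 at every update — with L1 (mean absolute error) as the
default training loss.  Batches are random LR/HR patch pairs drawn from the
training split, augmented with the dihedral-8 group; validation PSNR is
logged periodically and the best-validation checkpoint is kept.  Runs are
reproducible from the config seed and resumable from a checkpoint that
stores the optimizer state alongside the weights.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .data import (augment, center_crop_to_multiple, degrade, read_image,
                   read_manifest, sample_patch_pair)
from .evaluation import evaluate
from .model import STAN, ModelConfig, save_checkpoint, load_checkpoint


@dataclass
class TrainConfig:
    initial_lr: float = 2e-4
    lr_decay_per_update: float = 0.999
    batch_size: int = 8
    total_updates: int = 2000
    loss_kind: str = "l1"          # "l1" or "mse"
    seed: int = 0
    patch_size: int = 16           # LR-space patch side (desk-scale default)
    checkpoint_every: int = 500
    log_every: int = 50
    val_every: int = 250
    grad_clip: float = 1.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self):
        if not 0 < self.lr_decay_per_update <= 1:
            raise ValueError("lr_decay_per_update must lie in (0, 1]")
        if self.batch_size < 1 or self.total_updates < 0:
            raise ValueError("batch_size must be >= 1 and total_updates >= 0")
        if self.loss_kind not in ("l1", "mse"):
            raise ValueError("loss_kind must be 'l1' or 'mse'")


def lr_at(step: int, cfg: TrainConfig) -> float:
    """Learning rate after `step` updates: initial_lr * decay**step."""
    if step < 0:
        raise ValueError("step must be >= 0")
    return cfg.initial_lr * cfg.lr_decay_per_update ** step


def loss(pred: np.ndarray, target: np.ndarray, kind: str = "l1") -> float:
    """Mean absolute (L1) or mean squared error over all pixels/channels."""
    value, _ = loss_and_grad(pred, target, kind)
    return value


def loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str = "l1"):
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    n = diff.size
    if kind == "l1":
        return float(np.mean(np.abs(diff))), (np.sign(diff) / n).astype(pred.dtype)
    if kind == "mse":
        return float(np.mean(diff * diff)), (2.0 * diff / n).astype(pred.dtype)
    raise ValueError(f"unknown loss kind {kind!r}")


def train_step(model: STAN, lr_batch: np.ndarray, hr_batch: np.ndarray,
               opt: nn.Adam, cfg: TrainConfig, step: int) -> float:
    """One forward/backward/Adam update at lr_at(step); returns the loss."""
    model.zero_grad()
    pred = model.forward(lr_batch)
    value, grad = loss_and_grad(pred, hr_batch, cfg.loss_kind)
    if not np.isfinite(value):
        raise RuntimeError(f"non-finite loss {value} at step {step}")
    model.backward(grad)
    opt.step(lr_at(step, cfg))
    return value


class _PairSampler:
    """In-memory cache of (HR, LR) images for one split, with patch sampling."""

    def __init__(self, entries, scale):
        if not entries:
            raise ValueError("empty split")
        self.scale = scale
        self.items = []
        for e in entries:
            hr = read_image(e["path"])
            lr = degrade(hr, scale)
            # keep the center-cropped HR that degrade() actually used
            hr = center_crop_to_multiple(hr, scale)
            self.items.append((str(e["path"]), hr, lr))

    def batch(self, rng, patch_size, batch_size):
        lrs, hrs = [], []
        for _ in range(batch_size):
            _, hr, lr = self.items[int(rng.integers(0, len(self.items)))]
            pair = sample_patch_pair(hr, lr, patch_size, self.scale, rng)
            pair = augment(pair, rng)
            lrs.append(pair.lr.data)
            hrs.append(pair.hr.data)
        return np.stack(lrs), np.stack(hrs)


def fit(model_cfg: ModelConfig, train_cfg: TrainConfig, manifest_path,
        out_dir, resume=None, log_fn=None) -> Path:
    """Train on a dataset manifest; returns the path of the best checkpoint.

    Writes ``metrics.csv`` (step, lr, loss, val_psnr), ``last.npz`` (model +
    optimizer state, resumable) and ``best.npz`` (highest validation PSNR)
    under ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = read_manifest(manifest_path)
    train_entries = [e for e in entries if e["split"] == "train"]
    val_entries = [e for e in entries if e["split"] == "val"]
    if not train_entries or not val_entries:
        raise ValueError("manifest must contain non-empty train and val splits")
    sampler = _PairSampler(train_entries, model_cfg.scale)

    start_step = 0
    best_psnr = -np.inf
    if resume is not None:
        model, extra = load_checkpoint(resume)
        if asdict(model.config) != asdict(model_cfg):
            raise ValueError("resume checkpoint config differs from model_cfg")
        opt = nn.Adam(model.parameters(), train_cfg.adam_beta1,
                      train_cfg.adam_beta2, train_cfg.adam_eps,
                      grad_clip=train_cfg.grad_clip)
        opt_state = {k[len("opt_"):]: v for k, v in extra.items()
                     if k.startswith("opt_")}
        if opt_state:
            opt.load_state_dict(opt_state)
        start_step = int(extra.get("step", 0))
        best_psnr = float(extra.get("best_psnr", -np.inf))
    else:
        model = STAN(model_cfg)
        opt = nn.Adam(model.parameters(), train_cfg.adam_beta1,
                      train_cfg.adam_beta2, train_cfg.adam_eps,
                      grad_clip=train_cfg.grad_clip)

    metrics_path = out_dir / "metrics.csv"
    new_log = not metrics_path.exists() or resume is None
    log_fh = open(metrics_path, "w" if new_log else "a", newline="")
    logger = csv.writer(log_fh)
    if new_log:
        logger.writerow(["step", "lr", "loss", "val_psnr"])

    rng = np.random.default_rng(train_cfg.seed + start_step)
    running = []
    try:
        for step in range(start_step, train_cfg.total_updates):
            lr_b, hr_b = sampler.batch(rng, train_cfg.patch_size,
                                       train_cfg.batch_size)
            value = train_step(model, lr_b, hr_b, opt, train_cfg, step)
            running.append(value)
            done = step + 1
            is_val = done % train_cfg.val_every == 0 or done == train_cfg.total_updates
            val_psnr = ""
            if is_val:
                res = evaluate(model, manifest_path, model_cfg.scale, split="val")
                val_psnr = res.aggregate
                if val_psnr > best_psnr:
                    best_psnr = val_psnr
                    save_checkpoint(model, out_dir / "best.npz",
                                    {"step": done, "best_psnr": best_psnr})
            if is_val or done % train_cfg.log_every == 0:
                mean_loss = float(np.mean(running))
                running = []
                logger.writerow([done, lr_at(step, train_cfg), mean_loss, val_psnr])
                log_fh.flush()
                if log_fn:
                    log_fn(f"step {done}/{train_cfg.total_updates} "
                           f"loss {mean_loss:.5f}"
                           + (f" val_psnr {val_psnr:.3f}" if val_psnr != "" else ""))
            if done % train_cfg.checkpoint_every == 0 or done == train_cfg.total_updates:
                extra = {"step": done, "best_psnr": best_psnr}
                extra.update({f"opt_{k}": v for k, v in opt.state_dict().items()})
                save_checkpoint(model, out_dir / "last.npz", extra)
    finally:
        log_fh.close()
    if not (out_dir / "best.npz").exists():
        save_checkpoint(model, out_dir / "best.npz",
                        {"step": train_cfg.total_updates, "best_psnr": best_psnr})
    return out_dir / "best.npz"
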