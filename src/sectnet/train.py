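"""Training and prediction loops.

The total objective is the sum of the configured loss on the coarse and
refined masks, ``L(coarse) + L(refined)`` with equal weights: the
coarse mask must receive direct supervision to be a meaningful guide
for the refinement decoder.  The refined mask is the reported
prediction, and the checkpoint with the highest validation Dice on it
is kept as ``best.npz``.

Runs are fully seeded (parameter init via the model seed, batch order
via the train seed); execution is single-threaded numpy, so equal
seeds give bit-identical histories.
"""

from __future__ import annotations

import csv
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .dataset import SegDataset
from .losses import make_loss
from .metrics import MetricReport, confusion, dice_coef, evaluate
from .network import ModelConfig, SECTNet, build_model, save_checkpoint
from .optim import make_optimizer

__all__ = ["TrainConfig", "TrainHistory", "train", "predict"]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    learning_rate: float = 0.001
    epochs: int = 200
    optimizer: str = "adam"
    loss: str = "dice"
    seed: int = 0
    checkpoint_dir: str | None = None
    val_interval: int = 1
    augment: bool = False
    verbose: bool = False

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        make_loss(self.loss)  # validate names eagerly


@dataclass
class TrainHistory:
    """One record per completed epoch."""

    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        if not self.records:
            return
        keys = list(self.records[0].keys())
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(self.records)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield order[lo:lo + batch_size]


def _augment(images: np.ndarray, masks: np.ndarray, rng: np.random.Generator):
    """Random flips and 90-degree rotations, applied jointly."""
    for i in range(images.shape[0]):
        if rng.random() < 0.5:
            images[i] = images[i, :, ::-1]
            masks[i] = masks[i, :, ::-1]
        k = int(rng.integers(0, 4))
        if k:
            images[i] = np.rot90(images[i], k)
            masks[i] = np.rot90(masks[i], k)
    return images, masks


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, dataset: SegDataset,
          model: SECTNet | None = None) -> tuple[SECTNet, TrainHistory]:
    """Optimize ``L(coarse) + L(refined)`` over the train split.

    Returns the trained model (final parameters) and the history; the
    best-validation-Dice checkpoint is saved to
    ``train_cfg.checkpoint_dir / "best.npz"`` when a directory is set.
    """
    if not dataset.train:
        raise ValueError("dataset has an empty train partition")
    if not dataset.val:
        raise ValueError("dataset has an empty val partition")
    model = model if model is not None else build_model(model_cfg)
    loss_fn = make_loss(train_cfg.loss)
    opt = make_optimizer(train_cfg.optimizer, model.parameters(), train_cfg.learning_rate)
    rng = np.random.default_rng(train_cfg.seed)

    images = np.stack([s.image for s in dataset.train])[:, None].astype(np.float32)
    masks = np.stack([s.mask for s in dataset.train])[:, None].astype(np.float32)

    ckpt_dir = Path(train_cfg.checkpoint_dir) if train_cfg.checkpoint_dir else None
    if ckpt_dir:
        ckpt_dir.mkdir(parents=True, exist_ok=True)
    history = TrainHistory()
    best_val_dice = -1.0

    for epoch in range(1, train_cfg.epochs + 1):
        t0 = time.time()
        model.train()
        epoch_loss = 0.0
        epoch_dice = 0.0
        epoch_acc = 0.0
        n_batches = 0
        for idx in _batches(len(images), train_cfg.batch_size, rng):
            xb, yb = images[idx].copy(), masks[idx].copy()
            if train_cfg.augment:
                xb, yb = _augment(xb, yb, rng)
            out = model(Tensor(xb))
            loss = loss_fn(out.coarse, yb) + loss_fn(out.refined, yb)
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            pred = out.refined.data
            c = confusion(pred, yb)
            epoch_dice += dice_coef(c)
            epoch_acc += (c.tp + c.tn) / c.total
            n_batches += 1
        record = {
            "epoch": epoch,
            "train_loss": epoch_loss / n_batches,
            "train_dice": epoch_dice / n_batches,
            "train_pixel_acc": epoch_acc / n_batches,
            "seconds": round(time.time() - t0, 3),
        }
        if epoch % train_cfg.val_interval == 0 or epoch == train_cfg.epochs:
            val_report = evaluate(model, dataset.val, batch_size=train_cfg.batch_size)
            val_dice = val_report.summary()["dice"]["mean"]
            record["val_dice"] = val_dice
            if val_dice > best_val_dice:
                best_val_dice = val_dice
                if ckpt_dir:
                    save_checkpoint(model, ckpt_dir / "best.npz")
        history.records.append(record)
        msg = " ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                       for k, v in record.items())
        if ckpt_dir:
            stamp = time.strftime("%Y-%m-%d %H:%M:%S")
            with open(ckpt_dir / "train.log", "a") as fh:
                fh.write(f"[{stamp}] {msg}\n")
        if train_cfg.verbose:
            print(msg, flush=True)

    if ckpt_dir:
        save_checkpoint(model, ckpt_dir / "last.npz")
        history.to_csv(ckpt_dir / "history.csv")
    return model, history


def predict(model: SECTNet, images: np.ndarray, batch_size: int = 4,
            threshold: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Refined probability maps and thresholded binary masks for a stack
    of (N, H, W) images."""
    model.eval()
    probs = []
    for lo in range(0, images.shape[0], batch_size):
        batch = images[lo:lo + batch_size][:, None].astype(np.float32)
        probs.append(model(Tensor(batch)).refined.data[:, 0])
    prob = np.concatenate(probs, axis=0)
    return prob, (prob >= threshold).astype(np.uint8)
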