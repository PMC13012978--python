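"""Pixel-overlap evaluation metrics and report aggregation.

Metrics are computed from per-image confusion counts:

    Dice    = 2TP / (2TP + FN + FP)
    Jaccard = TP / (TP + FN + FP)
    Mcc     = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FN)(TN+FP))

Zero-denominator conventions: an image with an empty target and an
empty prediction scores Dice = Jaccard = 1 (all negatives correct) and
Mcc = 0; any other zero Mcc denominator also yields 0.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "dice_coef", "jaccard", "mcc",
           "MetricReport", "evaluate"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred, target, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts of (pred >= threshold) against a binary target."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    pred = np.asarray(getattr(pred, "data", pred))
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")
    p = pred >= threshold
    t = target >= 0.5
    return ConfusionCounts(
        tp=int(np.count_nonzero(p & t)),
        fp=int(np.count_nonzero(p & ~t)),
        fn=int(np.count_nonzero(~p & t)),
        tn=int(np.count_nonzero(~p & ~t)),
    )


def dice_coef(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return 2 * c.tp / denom


def jaccard(c: ConfusionCounts) -> float:
    denom = c.tp + c.fn + c.fp
    if denom == 0:
        return 1.0
    return c.tp / denom


def mcc(c: ConfusionCounts) -> float:
    denom = math.sqrt(float(c.tp + c.fn) * (c.tp + c.fp) * (c.tn + c.fn) * (c.tn + c.fp))
    if denom == 0.0:
        return 0.0
    return (c.tp * c.tn - c.fp * c.fn) / denom


@dataclass
class MetricReport:
    """Per-image Dice / Mcc / Jaccard with mean and standard deviation."""

    dice: list[float]
    mcc: list[float]
    jaccard: list[float]

    def __len__(self) -> int:
        return len(self.dice)

    def summary(self) -> dict[str, dict[str, float]]:
        out = {}
        for name, values in (("dice", self.dice), ("mcc", self.mcc),
                             ("jaccard", self.jaccard)):
            arr = np.asarray(values, dtype=np.float64)
            out[name] = {"mean": float(arr.mean()), "std": float(arr.std())}
        return out

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["image", "dice", "mcc", "jaccard"])
            for i, (d, m, j) in enumerate(zip(self.dice, self.mcc, self.jaccard)):
                writer.writerow([i, f"{d:.6f}", f"{m:.6f}", f"{j:.6f}"])

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def evaluate(model, samples, threshold: float = 0.5, batch_size: int = 4) -> MetricReport:
    """Per-image metrics of the model's refined mask over a list of samples.

    ``samples`` is an iterable of objects with ``image`` (2-D float
    array in [0, 1]) and ``mask`` (2-D binary array) attributes.
    The model is run in eval mode; inputs are batched for speed but
    metrics are strictly per image.
    """
    from .autodiff import Tensor

    samples = list(samples)
    if not samples:
        raise ValueError("evaluate() requires a non-empty dataset")
    was_training = model.training
    model.eval()
    report = MetricReport([], [], [])
    try:
        for lo in range(0, len(samples), batch_size):
            chunk = samples[lo:lo + batch_size]
            batch = np.stack([s.image for s in chunk])[:, None].astype(np.float32)
            preds = model(Tensor(batch)).refined.data[:, 0]
            for s, p in zip(chunk, preds):
                c = confusion(p, s.mask, threshold)
                report.dice.append(dice_coef(c))
                report.mcc.append(mcc(c))
                report.jaccard.append(jaccard(c))
    finally:
        model.train(was_training)
    return report
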