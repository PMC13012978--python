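"""Losses and evaluation metrics against closed forms and a pixel-loop
confusion oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sectnet.autodiff import Tensor
from sectnet.losses import bce_loss, dice_loss, hausdorff_loss, make_loss, tversky_loss
from sectnet.metrics import (ConfusionCounts, MetricReport, confusion, dice_coef,
                             evaluate, jaccard, mcc)


def _loop_confusion(pred, target, thr=0.5):
    """Independent pixel-by-pixel confusion oracle."""
    tp = fp = fn = tn = 0
    for p, t in zip(np.asarray(pred).ravel(), np.asarray(target).ravel()):
        if p >= thr and t >= 0.5:
            tp += 1
        elif p >= thr:
            fp += 1
        elif t >= 0.5:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_dice_loss_perfect_disjoint_and_hand_case():
    y = np.zeros((1, 1, 4, 4), np.float32)
    y[0, 0, :2] = 1.0
    assert dice_loss(Tensor(y), y).item() == pytest.approx(0.0, abs=1e-6)
    disjoint = 1.0 - y
    assert dice_loss(Tensor(disjoint), y).item() == pytest.approx(1.0, abs=1e-6)
    # y = (1, 0), p = (0.5, 0.5): 1 - 2*0.5 / (1 + 0.5) = 1/3
    got = dice_loss(Tensor(np.array([0.5, 0.5], np.float32)),
                    np.array([1.0, 0.0], np.float32)).item()
    assert got == pytest.approx(1.0 / 3.0, abs=1e-5)


def test_bce_loss_closed_forms():
    y = np.array([1.0, 0.0], np.float32)
    half = Tensor(np.full(2, 0.5, np.float32))
    assert bce_loss(half, y).item() == pytest.approx(math.log(2.0), rel=1e-5)
    near = Tensor(np.array([1.0, 0.0], np.float32))
    assert bce_loss(near, y).item() < 1e-5
    # y=1, p=0.8 -> -ln 0.8
    got = bce_loss(Tensor(np.array([0.8], np.float32)), np.array([1.0], np.float32)).item()
    assert got == pytest.approx(-math.log(0.8), rel=1e-4)


def test_tversky_loss_reduces_to_dice_on_binary_masks(rng):
    y = (rng.random((3, 1, 8, 8)) < 0.3).astype(np.float32)
    assert tversky_loss(Tensor(y), y, 0.5, 0.5).item() == pytest.approx(0.0, abs=1e-5)
    p = (rng.random((3, 1, 8, 8)) < 0.3).astype(np.float32)
    tv = tversky_loss(Tensor(p), y, 0.5, 0.5).item()
    dl = dice_loss(Tensor(p), y).item()
    assert tv == pytest.approx(dl, abs=1e-5)  # binary: sum p^2 = sum p
    disjoint_y = np.zeros_like(y)
    disjoint_y[..., :1] = 1.0
    disjoint_p = np.zeros_like(y)
    disjoint_p[..., 1:2] = 1.0
    assert tversky_loss(Tensor(disjoint_p), disjoint_y).item() == pytest.approx(1.0, abs=1e-5)


def test_hausdorff_loss_distance_sensitivity():
    y = np.zeros((1, 1, 32, 32), np.float32)
    y[0, 0, 10:20, 10:20] = 1.0
    assert hausdorff_loss(Tensor(y), y).item() == pytest.approx(0.0, abs=1e-9)
    shift1 = np.roll(y, 1, axis=3)
    shift2 = np.roll(y, 2, axis=3)
    l1 = hausdorff_loss(Tensor(shift1), y).item()
    l2 = hausdorff_loss(Tensor(shift2), y).item()
    assert 0.0 < l1 < l2
    empty = np.zeros_like(y)
    assert hausdorff_loss(Tensor(empty), y).item() > 0.0
    assert hausdorff_loss(Tensor(empty), empty).item() == pytest.approx(0.0)


def test_loss_registry_rejects_unknown_names():
    with pytest.raises(ValueError, match="unknown loss"):
        make_loss("focal")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def test_worked_confusion_example_exactly():
    c = ConfusionCounts(tp=8, fp=2, fn=2, tn=88)
    assert dice_coef(c) == pytest.approx(0.8)
    assert jaccard(c) == pytest.approx(8 / 12)
    assert mcc(c) == pytest.approx(700 / 900)


def test_perfect_and_degenerate_conventions():
    perfect = ConfusionCounts(tp=5, fp=0, fn=0, tn=5)
    assert dice_coef(perfect) == jaccard(perfect) == 1.0
    assert mcc(perfect) == pytest.approx(1.0)
    empty = ConfusionCounts(tp=0, fp=0, fn=0, tn=16)
    assert dice_coef(empty) == jaccard(empty) == 1.0
    assert mcc(empty) == 0.0


def test_confusion_counts_enumeration_and_partition(rng):
    pred = np.ones((2, 2), np.float32)
    target = np.array([[1, 1], [0, 0]], np.float32)
    c = confusion(pred, target)
    assert (c.tp, c.fp, c.fn, c.tn) == (2, 2, 0, 0)
    p = rng.random((16, 16))
    t = (rng.random((16, 16)) < 0.4).astype(np.float32)
    c = confusion(p, t)
    assert c.total == 256


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_metric_invariants_on_random_masks(seed):
    rng = np.random.default_rng(seed)
    p = (rng.random((12, 12)) < rng.uniform(0, 1)).astype(np.float32)
    t = (rng.random((12, 12)) < rng.uniform(0, 1)).astype(np.float32)
    c = confusion(p, t)
    d, j, m = dice_coef(c), jaccard(c), mcc(c)
    assert 0.0 <= d <= 1.0 and 0.0 <= j <= 1.0 and -1.0 <= m <= 1.0
    assert j <= d + 1e-12
    assert j == pytest.approx(d / (2.0 - d), abs=1e-12)


def test_metrics_agree_with_pixel_loop_oracle(rng):
    for _ in range(100):
        p = rng.random((16, 16))
        t = (rng.random((16, 16)) < 0.5).astype(np.float32)
        c = confusion(p, t)
        tp, fp, fn, tn = _loop_confusion(p, t)
        assert (c.tp, c.fp, c.fn, c.tn) == (tp, fp, fn, tn)
        denom = 2 * tp + fn + fp
        expect_dice = 1.0 if denom == 0 else 2 * tp / denom
        assert dice_coef(c) == pytest.approx(expect_dice, abs=1e-9)


def test_dice_loss_complements_dice_coef_on_binary_preds(rng):
    p = (rng.random((1, 1, 16, 16)) < 0.4).astype(np.float32)
    t = (rng.random((1, 1, 16, 16)) < 0.4).astype(np.float32)
    loss = dice_loss(Tensor(p), t).item()
    coef = dice_coef(confusion(p, t))
    assert loss == pytest.approx(1.0 - coef, abs=1e-4)


def test_confusion_threshold_validation():
    with pytest.raises(ValueError, match="threshold"):
        confusion(np.zeros((2, 2)), np.zeros((2, 2)), threshold=1.5)


# ---------------------------------------------------------------------------
# evaluate / MetricReport
# ---------------------------------------------------------------------------

class _OracleModel:
    """Stub model that returns the ground truth as its refined mask."""

    training = False

    def __init__(self, masks):
        self._masks = {m.tobytes(): m for m in masks}

    def eval(self):
        return self

    def train(self, mode=True):
        return self

    def __call__(self, batch):
        from types import SimpleNamespace
        data = batch.data
        out = np.stack([self._lookup(img) for img in data[:, 0]])[:, None]
        return SimpleNamespace(refined=Tensor(out), coarse=Tensor(out))

    def _lookup(self, img):
        # image encodes the mask directly in this stub
        return (img >= 0.5).astype(np.float32)


def test_evaluate_perfect_oracle_and_report_shape(rng, tmp_path):
    from sectnet.dataset import Sample
    masks = [(rng.random((8, 8)) < 0.4).astype(np.uint8) for _ in range(5)]
    samples = [Sample(image=m.astype(np.float32), mask=m, patient_id=i)
               for i, m in enumerate(masks)]
    report = evaluate(_OracleModel(masks), samples)
    assert len(report) == 5
    summary = report.summary()
    assert summary["dice"]["mean"] == pytest.approx(1.0)
    assert summary["dice"]["std"] == pytest.approx(0.0)
    report.to_csv(tmp_path / "per_image.csv")
    report.to_json(tmp_path / "summary.json")
    assert (tmp_path / "per_image.csv").read_text().count("\n") == 6  # header + 5 rows


def test_evaluate_matches_per_image_recomputation(rng):
    """evaluate() must agree with an independent per-image confusion loop."""
    from sectnet.dataset import Sample
    from sectnet.network import ModelConfig, build_model

    model = build_model(ModelConfig(input_side=32, base_width=4, seed=0,
                                    use_sectm=False, use_dfcm=False))
    samples = [Sample(image=rng.random((32, 32)).astype(np.float32),
                      mask=(rng.random((32, 32)) < 0.3).astype(np.uint8),
                      patient_id=i) for i in range(3)]
    report = evaluate(model, samples)
    model.eval()
    for s, d, m, j in zip(samples, report.dice, report.mcc, report.jaccard):
        pred = model(Tensor(s.image[None, None])).refined.data[0, 0]
        tp, fp, fn, tn = _loop_confusion(pred, s.mask)
        c = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)
        assert d == pytest.approx(dice_coef(c), abs=1e-9)
        assert j == pytest.approx(jaccard(c), abs=1e-9)
        assert m == pytest.approx(mcc(c), abs=1e-9)


def test_evaluate_rejects_empty_dataset(rng):
    with pytest.raises(ValueError, match="non-empty"):
        evaluate(_OracleModel([]), [])
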