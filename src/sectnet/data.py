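"""Dataset readers and writers.

Two on-disk layouts are supported:

* a paired-PNG tree ``{split}/{patient}/{slice}_img.png`` /
  ``{slice}_mask.png`` with an ``index.csv`` (path, patient_id, split)
  — the layout the phantom generator writes;
* NIfTI image/mask volume pairs, sliced along axis 0, one patient per
  volume.

Images are scaled to [0, 1]; RGB inputs are converted to grayscale by
luminance average; masks are binarized at half their maximum.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from PIL import Image

from .dataset import Sample, SegDataset
from .nn import bilinear_resize
from .autodiff import Tensor

__all__ = ["write_dataset", "read_dataset", "load_image", "load_nifti_pair",
           "save_mask_png"]


def load_image(path) -> np.ndarray:
    """Read an image file as a float32 array in [0, 1] (grayscale)."""
    arr = np.asarray(Image.open(path), dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    return arr / 255.0


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    Image.fromarray(((np.asarray(mask) >= 0.5) * 255).astype(np.uint8)).save(path)


def save_probability_png(prob: np.ndarray, path) -> None:
    Image.fromarray(np.round(np.clip(prob, 0, 1) * 255).astype(np.uint8)).save(path)


def write_dataset(ds: SegDataset, root) -> Path:
    """Write a dataset as a paired-PNG tree with an index CSV."""
    root = Path(root)
    index_rows = []
    for split, samples in ds.splits.items():
        counters: dict = {}
        for s in samples:
            i = counters.get(s.patient_id, 0)
            counters[s.patient_id] = i + 1
            pdir = root / split / f"patient_{s.patient_id:04d}" \
                if isinstance(s.patient_id, int) else root / split / str(s.patient_id)
            pdir.mkdir(parents=True, exist_ok=True)
            img_path = pdir / f"{i:03d}_img.png"
            mask_path = pdir / f"{i:03d}_mask.png"
            Image.fromarray(np.round(s.image * 255).astype(np.uint8)).save(img_path)
            save_mask_png(s.mask, mask_path)
            index_rows.append([str(img_path.relative_to(root)), s.patient_id, split])
    with open(root / "index.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "patient_id", "split"])
        writer.writerows(index_rows)
    return root


def _resample(image: np.ndarray, side: int) -> np.ndarray:
    if image.shape == (side, side):
        return image.astype(np.float32)
    t = Tensor(image[None, None].astype(np.float32))
    return bilinear_resize(t, side, side).data[0, 0]


def load_nifti_pair(image_path, mask_path, side: int | None = None) -> list[Sample]:
    """Slice a NIfTI image/mask volume pair along axis 0 into samples.

    Intensities are min-max scaled to [0, 1] over the whole volume; the
    file stem is the patient id.
    """
    import nibabel as nib

    img_vol = np.asanyarray(nib.load(str(image_path)).dataobj).astype(np.float32)
    mask_vol = np.asanyarray(nib.load(str(mask_path)).dataobj).astype(np.float32)
    if img_vol.shape != mask_vol.shape:
        raise ValueError(f"image volume {img_vol.shape} != mask volume {mask_vol.shape}")
    lo, hi = float(img_vol.min()), float(img_vol.max())
    if hi > lo:
        img_vol = (img_vol - lo) / (hi - lo)
    mmax = mask_vol.max()
    patient = Path(str(image_path)).name.split(".")[0]
    samples = []
    for k in range(img_vol.shape[0]):
        image = img_vol[k]
        mask = (mask_vol[k] >= 0.5 * mmax).astype(np.uint8) if mmax > 0 \
            else np.zeros_like(mask_vol[k], dtype=np.uint8)
        if side is not None:
            image = _resample(image, side)
            mask = (_resample(mask.astype(np.float32), side) >= 0.5).astype(np.uint8)
        samples.append(Sample(image=image.astype(np.float32), mask=mask,
                              patient_id=patient))
    return samples


def read_dataset(root, side: int | None = None) -> SegDataset:
    """Read a dataset from a paired-PNG tree (via its index CSV).

    If ``index.csv`` is missing, the ``{split}/{patient}`` directory
    layout is walked directly.  ``side`` optionally resamples every
    slice to ``side x side``.
    """
    root = Path(root)
    ds = SegDataset(splits={})
    index = root / "index.csv"
    if index.exists():
        with open(index, newline="") as fh:
            rows = list(csv.DictReader(fh))
        entries = [(root / r["path"], r["patient_id"], r["split"]) for r in rows]
    else:
        entries = []
        for img_path in sorted(root.glob("*/*/*_img.png")):
            split = img_path.parent.parent.name
            entries.append((img_path, img_path.parent.name, split))
        if not entries:
            raise FileNotFoundError(f"no dataset found under {root}")
    for img_path, patient_id, split in entries:
        mask_path = Path(str(img_path).replace("_img.png", "_mask.png"))
        if not mask_path.exists():
            raise FileNotFoundError(f"missing mask for {img_path}")
        image = load_image(img_path)
        mask_arr = load_image(mask_path)
        if image.shape != mask_arr.shape:
            raise ValueError(f"image/mask shape mismatch for {img_path}")
        mask = (mask_arr >= 0.5 * max(mask_arr.max(), 1e-8)).astype(np.uint8)
        if side is not None:
            image = _resample(image, side)
            mask = (_resample(mask.astype(np.float32), side) >= 0.5).astype(np.uint8)
        try:
            pid: int | str = int(str(patient_id).replace("patient_", ""))
        except ValueError:
            pid = str(patient_id)
        ds.splits.setdefault(split, []).append(
            Sample(image=image.astype(np.float32), mask=mask, patient_id=pid))
    return ds
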