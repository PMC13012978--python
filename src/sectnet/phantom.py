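"""Deterministic CT-like phantom generator for liver-tumor segmentation.

Each sample is a grayscale slice containing an elliptical liver-like
organ on a dark background.  Lesions are star-convex polygons (random
radii over angular spokes) so their boundaries are irregular rather
than elliptic; their interiors carry a smooth multiplicative
heterogeneity field emulating uneven contrast enhancement; the image is
Gaussian-blurred so lesion boundaries are soft; and additive Gaussian
noise is applied last.  The ground-truth mask is the *un-blurred*
lesion union, so masks have crisp edges while images do not — the
combination of heterogeneous intensity, blurred boundaries and
irregular shape that makes clinical tumor segmentation hard.

Slices are grouped into synthetic "patients": slices of one patient
share the liver pose and a base lesion configuration, with per-slice
jitter.  This correlation makes patient-level splitting a real
leakage constraint rather than a formality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

from .dataset import Sample, SegDataset

__all__ = ["PhantomSpec", "generate_sample", "generate_patient", "generate_dataset"]


@dataclass(frozen=True)
class PhantomSpec:
    """Distributional parameters of the phantom generator.

    Intensities are on a [0, 1] scale.  ``tumor_contrast`` is the
    intensity *decrement* of lesions relative to the liver parenchyma
    (lesions are hypodense).  ``texture_amplitude`` bounds the liver's
    own low-frequency texture and is kept below half the minimum
    contrast so lesions remain separable in the noise- and blur-free
    limit.
    """

    image_side: int = 256
    tumors_per_image: tuple[int, int] = (1, 3)
    tumor_radius_px: tuple[float, float] = (6.0, 40.0)
    tumor_contrast: tuple[float, float] = (0.1, 0.4)
    boundary_blur_sigma: tuple[float, float] = (1.0, 4.0)
    noise_sigma: float = 0.03
    liver_ellipse_jitter: float = 0.08
    slices_per_patient: int = 8
    liver_intensity: float = 0.45
    background_intensity: float = 0.15
    texture_amplitude: float = 0.04
    spokes: int = 12

    def __post_init__(self):
        if self.tumor_radius_px[1] >= self.image_side / 2:
            raise ValueError("maximum tumor radius must be below image_side / 2")
        if self.tumor_contrast[0] <= self.noise_sigma:
            raise ValueError("minimum contrast must exceed noise_sigma "
                             "(lesions must be detectable in principle)")
        if self.tumors_per_image[0] < 0 or self.tumors_per_image[1] < self.tumors_per_image[0]:
            raise ValueError("invalid tumors_per_image range")


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _liver_pose(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    s = spec.image_side
    j = spec.liver_ellipse_jitter
    return {
        "center": (s * (0.50 + rng.uniform(-j, j) * 0.5),
                   s * (0.52 + rng.uniform(-j, j) * 0.5)),
        "axes": (s * 0.34 * (1 + rng.uniform(-j, j)),
                 s * 0.26 * (1 + rng.uniform(-j, j))),
        "angle": rng.uniform(-0.35, 0.35),
    }


def _liver_region(spec: PhantomSpec, pose: dict) -> np.ndarray:
    s = spec.image_side
    rr, cc = np.mgrid[0:s, 0:s].astype(np.float64)
    cy, cx = pose["center"]
    a, b = pose["axes"]
    t = pose["angle"]
    dy, dx = rr - cy, cc - cx
    u = dy * math.cos(t) + dx * math.sin(t)
    v = -dy * math.sin(t) + dx * math.cos(t)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _star_polygon(spec: PhantomSpec, rng: np.random.Generator,
                  center: tuple[float, float], radius: float) -> np.ndarray:
    """Rasterize a star-convex polygon into a boolean image mask."""
    angles = np.linspace(0.0, 2 * np.pi, spec.spokes, endpoint=False)
    angles = angles + rng.uniform(0, 2 * np.pi / spec.spokes)
    radii = radius * rng.uniform(0.7, 1.3, size=spec.spokes)
    rr = center[0] + radii * np.sin(angles)
    cc = center[1] + radii * np.cos(angles)
    out = np.zeros((spec.image_side, spec.image_side), dtype=bool)
    pr, pc = draw_polygon(rr, cc, shape=out.shape)
    out[pr, pc] = True
    return out


def _lesion_center(spec: PhantomSpec, rng: np.random.Generator, pose: dict,
                   radius: float) -> tuple[float, float]:
    """A point inside the liver ellipse with margin for the lesion radius."""
    a, b = pose["axes"]
    scale = max(0.05, 1.0 - 1.4 * radius / min(a, b))
    theta = rng.uniform(0, 2 * np.pi)
    rho = math.sqrt(rng.uniform(0, 1)) * scale
    u = rho * a * math.cos(theta)
    v = rho * b * math.sin(theta)
    t = pose["angle"]
    cy, cx = pose["center"]
    return (cy + u * math.cos(t) - v * math.sin(t),
            cx + u * math.sin(t) + v * math.cos(t))


def _smooth_field(spec: PhantomSpec, rng: np.random.Generator, sigma_frac: float = 0.08
                  ) -> np.ndarray:
    """Zero-mean low-frequency field normalized to [-1, 1]."""
    s = spec.image_side
    field = ndimage.gaussian_filter(rng.normal(size=(s, s)), sigma=max(s * sigma_frac, 1.0))
    peak = np.abs(field).max()
    return (field / peak) if peak > 0 else field


# --------------------------------------------------------------------------
# sample synthesis
# --------------------------------------------------------------------------

def _draw_lesions(spec: PhantomSpec, rng: np.random.Generator, pose: dict) -> list[dict]:
    lo, hi = spec.tumors_per_image
    n = int(rng.integers(lo, hi + 1))
    lesions = []
    for _ in range(n):
        radius = rng.uniform(*spec.tumor_radius_px)
        lesions.append({
            "radius": radius,
            "center": _lesion_center(spec, rng, pose, radius),
            "contrast": rng.uniform(*spec.tumor_contrast),
        })
    return lesions


def _render(spec: PhantomSpec, rng: np.random.Generator, pose: dict,
            lesions: list[dict], patient_id: int) -> Sample:
    liver = _liver_region(spec, pose)
    texture = _smooth_field(spec, rng) * spec.texture_amplitude
    image = np.full((spec.image_side, spec.image_side), spec.background_intensity,
                    dtype=np.float64)
    image[liver] = spec.liver_intensity + texture[liver]

    mask = np.zeros_like(liver)
    het = 0.7 + 0.3 * (0.5 * (_smooth_field(spec, rng, 0.05) + 1.0))  # in [0.7, 1.0]
    for lesion in lesions:
        shape = _star_polygon(spec, rng, lesion["center"], lesion["radius"]) & liver
        image[shape] = spec.liver_intensity - lesion["contrast"] * het[shape]
        mask |= shape

    sigma = rng.uniform(*spec.boundary_blur_sigma)
    if sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=sigma)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return Sample(image=image, mask=mask.astype(np.uint8), patient_id=patient_id,
                  liver=liver)


def generate_sample(spec: PhantomSpec, seed: int, patient_id: int = 0) -> Sample:
    """One phantom slice, bit-reproducible under ``seed``."""
    rng = np.random.default_rng(seed)
    pose = _liver_pose(spec, rng)
    lesions = _draw_lesions(spec, rng, pose)
    return _render(spec, rng, pose, lesions, patient_id)


def generate_patient(spec: PhantomSpec, seed: int, patient_id: int) -> list[Sample]:
    """All slices of one synthetic patient.

    The liver pose and a base lesion configuration are drawn once; each
    slice jitters lesion centers (a few pixels) and radii (about 10%)
    and receives independent texture, blur and noise.
    """
    rng = np.random.default_rng([seed, patient_id])
    pose = _liver_pose(spec, rng)
    base = _draw_lesions(spec, rng, pose)
    samples = []
    for _ in range(spec.slices_per_patient):
        jittered = [{
            "radius": lesion["radius"] * rng.uniform(0.9, 1.1),
            "center": (lesion["center"][0] + rng.uniform(-3, 3),
                       lesion["center"][1] + rng.uniform(-3, 3)),
            "contrast": lesion["contrast"],
        } for lesion in base]
        samples.append(_render(spec, rng, pose, jittered, patient_id))
    return samples


def generate_dataset(n_patients: int, spec: PhantomSpec, seed: int,
                     split: tuple[float, float, float] = (0.7, 0.15, 0.15)) -> SegDataset:
    """Patient-grouped dataset with leakage-free train/val/test partitions.

    Partition sizes are floor-based on the first two fractions; the
    remainder goes to the test split.  No patient spans two partitions.
    """
    if abs(sum(split) - 1.0) > 1e-6:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    if n_patients < 3:
        raise ValueError("need at least 3 patients for a 3-way patient-level split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_patients)
    n_train = int(math.floor(split[0] * n_patients))
    n_val = int(math.floor(split[1] * n_patients))
    # every nonzero fraction receives at least one patient
    if split[1] > 0 and n_val == 0:
        n_val = 1
        n_train = max(n_train - 1, 1)
    if split[2] > 0 and n_train + n_val >= n_patients:
        n_train = max(n_train - 1, 1)
    assignment = {}
    for rank, pid in enumerate(order):
        if rank < n_train:
            assignment[int(pid)] = "train"
        elif rank < n_train + n_val:
            assignment[int(pid)] = "val"
        else:
            assignment[int(pid)] = "test"
    ds = SegDataset(splits={"train": [], "val": [], "test": []})
    for pid in range(n_patients):
        ds.splits[assignment[pid]].extend(generate_patient(spec, seed, pid))
    return ds
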