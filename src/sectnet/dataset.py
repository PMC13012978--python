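"""In-memory dataset containers shared by the phantom generator and the
real-data readers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Sample", "SegDataset"]


@dataclass
class Sample:
    """One 2-D slice: image in [0, 1], binary mask, and the patient it
    belongs to.  ``liver`` (phantoms only) is the organ support region."""

    image: np.ndarray
    mask: np.ndarray
    patient_id: int | str
    liver: np.ndarray | None = None

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError(f"image shape {self.image.shape} != mask shape {self.mask.shape}")


@dataclass
class SegDataset:
    """Train/val/test partitions of samples, grouped by patient."""

    splits: dict[str, list[Sample]] = field(default_factory=dict)

    @property
    def train(self) -> list[Sample]:
        return self.splits.get("train", [])

    @property
    def val(self) -> list[Sample]:
        return self.splits.get("val", [])

    @property
    def test(self) -> list[Sample]:
        return self.splits.get("test", [])

    def patient_ids(self, split: str) -> set:
        return {s.patient_id for s in self.splits.get(split, [])}

    def __len__(self) -> int:
        return sum(len(v) for v in self.splits.values())
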