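"""Plant masks: threshold an NDblue (or any index) image, apply, compare.

A pixel belongs to the plant mask iff it is valid and its index value is
strictly greater than the threshold (default 0.1, chosen for the
range-normalized NDblue, whose output spans exactly 1.0 on every acquisition
day — which is what makes a single constant threshold workable).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .errors import EmptyMaskError, ValidationError
from .io_formats import GrayImage

DEFAULT_THRESHOLD = 0.1


@dataclass
class PlantMask:
    data: np.ndarray
    threshold: float
    source_index: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValidationError(f"mask must be 2-D, got shape {self.data.shape}")

    @property
    def area(self) -> int:
        return int(self.data.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def build_plant_mask(img: GrayImage, threshold: float = DEFAULT_THRESHOLD) -> PlantMask:
    """Mask of valid pixels with value strictly above ``threshold``.

    Raises :class:`EmptyMaskError` when nothing passes — the scene has no
    detectable plant.
    """
    if not img.valid.any():
        raise ValidationError("image has no valid pixels")
    data = img.valid & (np.nan_to_num(img.data, nan=-np.inf) > threshold)
    if not data.any():
        raise EmptyMaskError(
            f"no pixel of {img.name or 'image'} exceeds threshold {threshold}"
        )
    return PlantMask(data, threshold=float(threshold), source_index=img.name)


def apply_mask(img: GrayImage, mask: PlantMask) -> np.ndarray:
    """Values of valid masked pixels in row-major order."""
    if img.shape != mask.shape:
        raise ValidationError(f"image shape {img.shape} != mask shape {mask.shape}")
    return img.data[mask.data & img.valid]


def jaccard(a: PlantMask, b: PlantMask) -> float:
    union = np.logical_or(a.data, b.data).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a.data, b.data).sum() / union)


@dataclass
class MaskComparison:
    """Areas and pairwise Jaccard overlaps for a set of candidate masks."""

    masks: list[PlantMask]
    areas: list[int]
    overlap: np.ndarray  # symmetric Jaccard matrix


def compare_masks(candidates: list[tuple[GrayImage, float]]) -> MaskComparison:
    """Build each candidate mask and report areas plus pairwise Jaccard overlap.

    This is the quantitative skeleton of the mask-selection experiment: e.g.
    NDblue at 0.1 against NDVI at 0.15/0.25, judged by how stably each
    candidate covers the plant.
    """
    if not candidates:
        raise ValidationError("need at least one candidate")
    shapes = {img.shape for img, _ in candidates}
    if len(shapes) > 1:
        raise ValidationError(f"candidate images disagree on shape: {shapes}")
    masks = [build_plant_mask(img, thr) for img, thr in candidates]
    n = len(masks)
    overlap = np.eye(n)
    for i, j in combinations(range(n), 2):
        overlap[i, j] = overlap[j, i] = jaccard(masks[i], masks[j])
    return MaskComparison(masks=masks, areas=[m.area for m in masks], overlap=overlap)


def recovery_rates(mask: PlantMask, truth: np.ndarray) -> tuple[float, float]:
    """(fraction of truth pixels recovered, false-positive fraction of mask)."""
    truth = np.asarray(truth, dtype=bool)
    if truth.shape != mask.shape:
        raise ValidationError("truth mask shape mismatch")
    recovered = float((mask.data & truth).sum() / max(truth.sum(), 1))
    false_pos = float((mask.data & ~truth).sum() / max(mask.area, 1))
    return recovered, false_pos
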