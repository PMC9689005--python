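"""Histogram statistics of masked pixel values.

Each index image, restricted to the plant mask, is summarized by six
statistics of its (denoised) pixel histogram: min, max, mean, std, max−min
and the Shannon entropy of the binned values.  Denoising discards extreme
percentiles before anything else is computed — thermal images lose 1% at the
bottom and 5% at the top (hot background clutter), cube-derived indices lose
1% on both sides.

Training samples arise by subsampling: each sample is an independent random
subset of 10–20% of the mask pixels, so a single scene per day yields many
labeled feature vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .indices import BandMap, IndexName, compute_all_indices
from .io_formats import FEATURE_NAMES, FeatureTable, GrayImage
from .masking import DEFAULT_THRESHOLD, PlantMask, apply_mask, build_plant_mask

DEFAULT_N_BINS = 64
DEFAULT_SUBSAMPLE_FRACTION = 0.15


@dataclass(frozen=True)
class TrimSpec:
    """Percentiles removed from each end of the value distribution."""

    lower_pct: float
    upper_pct: float

    def __post_init__(self) -> None:
        if self.lower_pct < 0 or self.upper_pct < 0:
            raise ValidationError("trim percentages must be non-negative")
        if self.lower_pct + self.upper_pct >= 100:
            raise ValidationError("trim percentages must leave something behind")


#: §-style defaults: thermal images are noisier at the hot end.
TIR_TRIM = TrimSpec(lower_pct=1.0, upper_pct=5.0)
HSI_TRIM = TrimSpec(lower_pct=1.0, upper_pct=1.0)


def default_trims() -> dict[str, TrimSpec]:
    """Per-image-kind trimming defaults keyed by GrayImage.kind."""
    return {"TIR": TIR_TRIM, "index": HSI_TRIM, "channel": HSI_TRIM}


@dataclass(frozen=True)
class StatFeatures:
    """The six histogram statistics for one index sample; entropy in bits."""

    min: float
    max: float
    mean: float
    std: float
    max_min: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def trim_percentiles(values: Sequence[float], spec: TrimSpec) -> np.ndarray:
    """Keep values within [P_lower, P_(100−upper)] (linear-interpolation percentiles).

    Order is preserved.  If the window would empty the list, the single
    untrimmed median is returned instead, so callers never see an empty
    sample.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot trim an empty value list")
    lo, hi = np.percentile(values, [spec.lower_pct, 100.0 - spec.upper_pct])
    kept = values[(values >= lo) & (values <= hi)]
    if kept.size == 0:
        return np.array([float(np.median(values))])
    return kept


def shannon_entropy(values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> float:
    """Shannon entropy (bits) of the equal-width histogram over [min, max].

    A zero-range sample occupies a single bin and has zero entropy.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot compute entropy of an empty value list")
    if n_bins < 1:
        raise ValidationError("n_bins must be >= 1")
    vmin, vmax = float(values.min()), float(values.max())
    if vmin == vmax:
        return 0.0
    counts, _ = np.histogram(values, bins=n_bins, range=(vmin, vmax))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def compute_statistics(values: Sequence[float], n_bins: int = DEFAULT_N_BINS) -> StatFeatures:
    """Sample min/max/mean, population std (÷n), range, and histogram entropy."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("cannot summarize an empty value list")
    vmin, vmax = float(values.min()), float(values.max())
    return StatFeatures(
        min=vmin,
        max=vmax,
        mean=float(values.mean()),
        std=float(values.std()),
        max_min=vmax - vmin,
        entropy=shannon_entropy(values, n_bins),
    )


def extract_features(
    index_images: Mapping[IndexName, GrayImage],
    mask: PlantMask,
    trims: Mapping[str, TrimSpec] | None = None,
    n_bins: int = DEFAULT_N_BINS,
) -> dict[IndexName, StatFeatures]:
    """Masked values → trim → statistics, for every supplied index image."""
    if mask.area == 0:
        raise ValidationError("mask is empty")
    trims = dict(default_trims(), **(trims or {}))
    out: dict[IndexName, StatFeatures] = {}
    for name, img in index_images.items():
        values = apply_mask(img, mask)
        if values.size == 0:
            raise ValidationError(f"{img.name}: no valid pixels under the mask")
        kept = trim_percentiles(values, trims[img.kind])
        out[IndexName(name)] = compute_statistics(kept, n_bins)
    return out


def subsample_feature_dataset(
    scenes: Iterable,
    indices: Sequence[IndexName] | None = None,
    fraction: float = DEFAULT_SUBSAMPLE_FRACTION,
    samples_per_day: int = 100,
    trims: Mapping[str, TrimSpec] | None = None,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    bands: BandMap | None = None,
    mask_threshold: float = DEFAULT_THRESHOLD,
) -> FeatureTable:
    """Labeled feature table from per-day scenes by random mask-pixel subsets.

    For each scene the plant mask is rebuilt from its own NDblue image (the
    mask-selection machinery, re-run per day).  Each of the
    ``samples_per_day`` samples draws ``ceil(fraction * mask_area)`` mask
    pixels uniformly without replacement and computes the six statistics per
    index on that subset; trimming happens on the subset.  Deterministic
    under ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    if samples_per_day < 1:
        raise ValidationError("samples_per_day must be >= 1")
    trims = dict(default_trims(), **(trims or {}))
    rows: list[tuple] = []
    scenes = list(scenes)
    if not scenes:
        raise ValidationError("no scenes supplied")
    for scene in scenes:
        images = compute_all_indices(scene.cube, tir=scene.tir, bands=bands)
        if indices is not None:
            images = {IndexName(n): images[IndexName(n)] for n in indices}
        ndblue = images.get(IndexName.NDBLUE)
        if ndblue is None:
            from .indices import compute_index

            ndblue = compute_index(scene.cube, IndexName.NDBLUE, bands=bands)
        mask = build_plant_mask(ndblue, mask_threshold)
        if mask.area < 10:
            raise ValidationError(
                f"day {scene.day}: mask of {mask.area} pixels is too small to subsample"
            )
        pix = {name: apply_mask(img, mask) for name, img in images.items()}
        n_pix = mask.area
        k = math.ceil(fraction * n_pix)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(scene.day)]))
        for s in range(samples_per_day):
            sel = rng.choice(n_pix, size=k, replace=False)
            sample_id = f"d{scene.day:02d}_s{s:04d}"
            for name, values in pix.items():
                sub = values[sel]
                sub = sub[np.isfinite(sub)]
                if sub.size == 0:
                    raise ValidationError(f"{name}: subset has no valid pixels")
                img_kind = images[name].kind
                stats = compute_statistics(trim_percentiles(sub, trims[img_kind]), n_bins)
                for fname, value in stats.as_dict().items():
                    rows.append((sample_id, int(scene.day), IndexName(name).value, fname, value))
    frame = pd.DataFrame(rows, columns=list(FeatureTable.COLUMNS))
    return FeatureTable(frame)
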