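"""The ten single-channel "index" images computed per scene.

Besides the thermal image (passed through unchanged) and three raw visible
channels (R630, G550, B480), five classical vegetation indices are computed
from the cube, plus NDblue — a range-normalized green-minus-blue difference
built specifically for plant masking:

    NDVI   = (ρ800 − ρ680) / (ρ800 + ρ680)
    GNDVI  = (ρ800 − ρ550) / (ρ800 + ρ550)
    GCL    = ρ800 / ρ550 − 1
    SIPI   = (ρ800 − ρ450) / (ρ800 − ρ680)
    GI     = ρ550 / ρ630
    NDblue = (G550 − B450) / (max(G550 − B450) − min(G550 − B450))

NDblue's denominator is the image-wide range, so its output always spans
exactly 1.0 and a single fixed mask threshold works across acquisition days.
mNDblue = −(ρλ − ρ450)/(ρ850 + ρ450) (λ = 550 by default) is provided as the
un-normalized ancestor of NDblue.  Pixels where a per-pixel denominator
vanishes are flagged invalid (NaN) and ignored by masking and feature
extraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import BandMissingError, DegenerateImageError, ValidationError
from .io_formats import GrayImage, HyperCube


class IndexName(str, Enum):
    TIR = "TIR"
    NDVI = "NDVI"
    GNDVI = "GNDVI"
    GCL = "GCL"
    SIPI = "SIPI"
    GI = "GI"
    RED = "RED"
    GREEN = "GREEN"
    BLUE = "BLUE"
    NDBLUE = "NDblue"


#: Indices derived from the cube (everything except the thermal channel).
HSI_INDICES = tuple(n for n in IndexName if n is not IndexName.TIR)


@dataclass(frozen=True)
class BandMap:
    """Named target wavelengths (nm) and the resolution tolerance.

    ``mndblue_lambda`` is the λ of the mNDblue formula; 550 nm keeps it
    compatible with the green hyperspectral channel.
    """

    blue450: float = 450.0
    blue480: float = 480.0
    green550: float = 550.0
    red630: float = 630.0
    red680: float = 680.0
    nir800: float = 800.0
    nir850: float = 850.0
    mndblue_lambda: float = 550.0
    tolerance: float = 10.0


def nearest_channel(wavelengths: np.ndarray, target: float, tolerance: float = 10.0) -> int:
    """Index of the channel closest to ``target`` nm; ties go to the lower wavelength.

    Raises :class:`BandMissingError` when no channel lies within ``tolerance``.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    if wavelengths.ndim != 1 or len(wavelengths) == 0:
        raise ValidationError("wavelengths must be a non-empty 1-D vector")
    if not np.all(np.diff(wavelengths) > 0):
        raise ValidationError("wavelengths must be strictly increasing")
    dist = np.abs(wavelengths - target)
    pos = int(np.argmin(dist))  # argmin returns the first (lower-λ) minimum on ties
    if dist[pos] > tolerance:
        raise BandMissingError(
            f"no channel within {tolerance} nm of {target} nm "
            f"(closest: {wavelengths[pos]} nm)"
        )
    return pos


def _band(cube: HyperCube, target: float, tolerance: float) -> np.ndarray:
    return cube.channel(nearest_channel(cube.wavelengths, target, tolerance)).astype(float)


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(num.shape, np.nan)
    ok = den != 0
    out[ok] = num[ok] / den[ok]
    return out


def _range_normalize(diff: np.ndarray, what: str) -> np.ndarray:
    finite = diff[np.isfinite(diff)]
    if finite.size == 0:
        raise ValidationError(f"{what}: no valid pixels")
    rng = float(finite.max() - finite.min())
    if rng == 0.0:
        raise DegenerateImageError(f"{what}: image-wide range is zero")
    return diff / rng


def compute_index(
    cube: HyperCube,
    name: IndexName,
    bands: BandMap | None = None,
    tir: GrayImage | None = None,
) -> GrayImage:
    """Compute one index image from the cube (or pass the thermal image through)."""
    bands = bands or BandMap()
    name = IndexName(name)
    tol = bands.tolerance

    if name is IndexName.TIR:
        if tir is None:
            raise ValidationError("TIR index requested but no thermal image supplied")
        return GrayImage(tir.data.copy(), kind="TIR", name=IndexName.TIR.value)

    if name is IndexName.RED:
        data = _band(cube, bands.red630, tol)
        return GrayImage(data, kind="channel", name=name.value)
    if name is IndexName.GREEN:
        data = _band(cube, bands.green550, tol)
        return GrayImage(data, kind="channel", name=name.value)
    if name is IndexName.BLUE:
        data = _band(cube, bands.blue480, tol)
        return GrayImage(data, kind="channel", name=name.value)

    if name is IndexName.NDVI:
        nir, red = _band(cube, bands.nir800, tol), _band(cube, bands.red680, tol)
        data = _safe_ratio(nir - red, nir + red)
    elif name is IndexName.GNDVI:
        nir, green = _band(cube, bands.nir800, tol), _band(cube, bands.green550, tol)
        data = _safe_ratio(nir - green, nir + green)
    elif name is IndexName.GCL:
        nir, green = _band(cube, bands.nir800, tol), _band(cube, bands.green550, tol)
        data = _safe_ratio(nir, green) - 1.0
    elif name is IndexName.SIPI:
        nir = _band(cube, bands.nir800, tol)
        blue, red = _band(cube, bands.blue450, tol), _band(cube, bands.red680, tol)
        data = _safe_ratio(nir - blue, nir - red)
    elif name is IndexName.GI:
        green, red = _band(cube, bands.green550, tol), _band(cube, bands.red630, tol)
        data = _safe_ratio(green, red)
    elif name is IndexName.NDBLUE:
        diff = _band(cube, bands.green550, tol) - _band(cube, bands.blue450, tol)
        data = _range_normalize(diff, "NDblue")
    else:  # pragma: no cover - enum is exhaustive
        raise ValidationError(f"unknown index {name}")
    return GrayImage(data, kind="index", name=name.value)


def compute_all_indices(
    cube: HyperCube,
    tir: GrayImage | None = None,
    bands: BandMap | None = None,
) -> dict[IndexName, GrayImage]:
    """All ten index images (TIR included only when a thermal image is given)."""
    names = list(IndexName) if tir is not None else list(HSI_INDICES)
    return {n: compute_index(cube, n, bands=bands, tir=tir) for n in names}


def compute_mndblue(cube: HyperCube, bands: BandMap | None = None) -> GrayImage:
    """mNDblue = −(ρλ − ρ450) / (ρ850 + ρ450), the literature masking index."""
    bands = bands or BandMap()
    lam = _band(cube, bands.mndblue_lambda, bands.tolerance)
    b450 = _band(cube, bands.blue450, bands.tolerance)
    nir = _band(cube, bands.nir850, bands.tolerance)
    return GrayImage(-_safe_ratio(lam - b450, nir + b450), kind="index", name="mNDblue")


def compute_ndgb(red: GrayImage, green: GrayImage, blue: GrayImage) -> GrayImage:
    """NDGB = (G − B) / (max(G − B) − min(G − B)) for plain RGB channels."""
    if not (red.shape == green.shape == blue.shape):
        raise ValidationError(
            f"channel shapes differ: {red.shape}, {green.shape}, {blue.shape}"
        )
    data = _range_normalize(green.data - blue.data, "NDGB")
    return GrayImage(data, kind="index", name="NDGB")
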