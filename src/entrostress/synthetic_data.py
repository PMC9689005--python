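"""Synthetic co-registered hyperspectral + thermal scenes of drought-stressed wheat.

The generator emulates a pot experiment observed on a fixed set of key days.
Plant pixels are drawn from a per-day Gaussian mixture over reflectance
bands — the mixture components model sub-populations of plants entering
stress unevenly — and the background from a single soil/pot Gaussian whose
green-minus-blue contrast stays below the NDblue mask threshold.  The
thermal channel shares the raster (co-registered by construction) and
carries the canonical early-drought signal: mean leaf temperature rises by
about 0.2 °C by day 6, keeps rising monotonically to day 19, and breaks
trend by day 25 when compensatory capacity is exhausted.

Heterogeneity over days follows the observed stress trajectory: a mildly
heterogeneous initial canopy (day 1), homogenization while plants still grow
(day 3), rising diversity as stress entry begins unevenly (day 6 onward),
maximal heterogeneity during active drying (days 12–19), and reduced
diversity once most plants have withered (day 25).  This is what produces
the characteristic per-day histogram-entropy pattern downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ValidationError
from .io_formats import GrayImage, HyperCube

SHORT_DAYS = (1, 3, 6, 8, 12)
LONG_DAYS = (1, 3, 6, 8, 12, 19, 25)

#: Default wavelength grid (nm) — the bands every index needs, desk scale.
DEFAULT_WAVELENGTHS = (450.0, 480.0, 550.0, 630.0, 680.0, 700.0, 800.0, 850.0)
REQUIRED_BANDS = (450.0, 480.0, 550.0, 630.0, 680.0, 800.0, 850.0)

#: Canonical reflectance spectra on the default grid.
HEALTHY_REFLECTANCE = (0.04, 0.05, 0.15, 0.08, 0.05, 0.20, 0.48, 0.50)
DRY_REFLECTANCE = (0.06, 0.12, 0.25, 0.28, 0.27, 0.30, 0.34, 0.33)
#: Dark, slightly blue-tinted soil/pot background: green-blue contrast ~ -0.02
#: so NDblue stays below the 0.1 mask threshold.
SOIL_REFLECTANCE = (0.135, 0.125, 0.115, 0.14, 0.15, 0.155, 0.17, 0.18)

AMBIENT_TEMP_C = 24.0
SOIL_TEMP_OFFSET_C = 3.0  # dry soil runs hotter than the canopy
SOIL_TEMP_STD_C = 0.5
TIR_SUBPOP_DEGREES_PER_T = 1.5  # leaf warming per unit of stress progression


@dataclass
class StateSpec:
    """Distributional description of the canopy on one key day.

    ``offsets`` has one row per plant sub-population: a per-band shift added
    to ``mean``, realizing uneven stress entry.  ``tir_offsets`` is the
    matching per-sub-population leaf-temperature shift (°C).
    """

    day: int
    mean: np.ndarray  # (bands,) mixture-mean reflectance
    spread: np.ndarray  # (bands,) per-band std of each component
    weights: np.ndarray  # (k,) mixing weights, sum to 1
    offsets: np.ndarray  # (k, bands) per-component mean shifts
    tir_mean: float  # mean canopy temperature offset above ambient, °C
    tir_std: float
    tir_offsets: np.ndarray = field(default=None)  # (k,) per-component °C shifts
    spread_scales: np.ndarray = field(default=None)  # (k,) per-component spread multipliers

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.spread = np.asarray(self.spread, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.offsets = np.atleast_2d(np.asarray(self.offsets, dtype=float))
        if self.tir_offsets is None:
            self.tir_offsets = np.zeros(len(self.weights))
        self.tir_offsets = np.asarray(self.tir_offsets, dtype=float)
        if self.spread_scales is None:
            self.spread_scales = np.ones(len(self.weights))
        self.spread_scales = np.asarray(self.spread_scales, dtype=float)
        if len(self.spread_scales) != len(self.weights) or np.any(self.spread_scales <= 0):
            raise ValidationError("spread_scales must be positive, one per sub-population")
        if np.any(self.spread <= 0):
            raise ValidationError("spread must be positive in every band")
        if not np.isclose(self.weights.sum(), 1.0):
            raise ValidationError("mixing weights must sum to 1")
        if self.offsets.shape != (len(self.weights), len(self.mean)):
            raise ValidationError("offsets must be (n_subpops, n_bands)")
        if len(self.tir_offsets) != len(self.weights):
            raise ValidationError("tir_offsets must match weights")
        if self.day not in LONG_DAYS:
            raise ValidationError(f"day {self.day} is not a key day {LONG_DAYS}")

    @property
    def n_subpops(self) -> int:
        return len(self.weights)


@dataclass
class SceneConfig:
    """Raster geometry, band grid and background model for one scene."""

    height: int = 64
    width: int = 64
    wavelengths: tuple = DEFAULT_WAVELENGTHS
    plant_fraction: float = 0.3
    soil_reflectance: tuple = SOIL_REFLECTANCE
    soil_std: float = 0.008
    noise_std: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        self.wavelengths = tuple(float(w) for w in self.wavelengths)
        if not (0 < self.plant_fraction < 1):
            raise ValidationError("plant_fraction must be in (0, 1)")
        wl = np.asarray(self.wavelengths)
        for band in REQUIRED_BANDS:
            if np.abs(wl - band).min() > 10.0:
                raise ValidationError(f"wavelength grid misses required band {band} nm")
        if len(self.soil_reflectance) != len(self.wavelengths):
            raise ValidationError("soil_reflectance length must match wavelengths")


@dataclass
class SyntheticScene:
    cube: HyperCube
    tir: GrayImage
    truth_mask: np.ndarray
    day: int

    def __post_init__(self) -> None:
        self.truth_mask = np.asarray(self.truth_mask, dtype=bool)
        h, w, _ = self.cube.shape
        if self.tir.shape != (h, w) or self.truth_mask.shape != (h, w):
            raise ValidationError("cube, TIR and truth mask must share spatial dims")
        if not self.truth_mask.any():
            raise ValidationError("truth mask is empty")


# ---------------------------------------------------------------------------
# Default state trajectory


def _base_sigma(mean: np.ndarray) -> np.ndarray:
    # within-component std grows with reflectance; floor keeps dark bands noisy
    return 0.04 * mean + 0.003


#: Per-day trajectory parameters, calibrated once to realize the ordinal
#: entropy/spread pattern of the stress states (see docs/methods.md):
#: (stress progression t, spread scale, sub-population t-offsets, weights,
#: per-sub-population spread multipliers).  Day 3 is a leptokurtic scale
#: mixture (tight core, broad tail): the homogenized growing canopy with a
#: few laggards, which is what pushes its histogram entropy below day 1.
_TRAJECTORY = {
    1: (0.00, 1.0, (-0.06, 0.06), (0.5, 0.5), (1.0, 1.0)),
    3: (0.00, 0.8, (0.0, 0.0), (0.65, 0.35), (0.5, 1.7)),
    6: (0.08, 1.0, (-0.12, 0.19), (0.5, 0.5), (1.0, 1.0)),
    8: (0.15, 1.1, (-0.25, 0.00, 0.25), (0.35, 0.35, 0.3), (1.0, 1.0, 1.0)),
    12: (0.30, 1.3, (-0.36, 0.00, 0.36), (0.35, 0.35, 0.3), (1.0, 1.0, 1.0)),
    19: (0.55, 1.6, (-0.49, 0.00, 0.49), (0.33, 0.34, 0.33), (1.0, 1.0, 1.0)),
    25: (0.75, 1.2, (-0.12, 0.12), (0.5, 0.5), (0.6, 1.5)),
}

#: Canopy temperature offset above ambient per key day (°C).  +0.2 °C by
#: day 6, strictly increasing to day 19, trend break at day 25.
_TIR_MEAN = {1: 0.0, 3: 0.05, 6: 0.2, 8: 0.35, 12: 0.6, 19: 1.0, 25: 0.8}
_TIR_STD = {1: 0.15, 3: 0.12, 6: 0.2, 8: 0.25, 12: 0.35, 19: 0.45, 25: 0.3}

#: Mean-matched variant: every day shares the same mixture mean; only
#: spread/shape/width change.  (spread scale, component multipliers, weights)
#: — multipliers are applied to the per-band sigma direction and weighted to
#: zero mean, so 'mean'-type features carry no day signal.
_MEAN_MATCHED = {
    1: (1.0, (-0.7, 0.7), (0.5, 0.5), (1.0, 1.0)),
    3: (0.8, (0.0, 0.0), (0.7, 0.3), (0.45, 1.8)),
    6: (1.15, (-1.4, 1.4), (0.5, 0.5), (1.0, 1.0)),
    8: (1.0, (-2.8, 2.8), (0.5, 0.5), (1.0, 1.0)),
    12: (1.3, (-2.5, 0.0, 2.5), (0.3, 0.4, 0.3), (1.0, 1.0, 1.0)),
    19: (1.7, (-2.3, 0.0, 2.3), (0.3, 0.4, 0.3), (1.0, 1.0, 1.0)),
    25: (1.3, (0.0, 0.0), (0.55, 0.45), (0.5, 1.45)),
}


def default_state_specs(period: str = "long", mean_matched: bool = False) -> list[StateSpec]:
    """The per-day state specifications for the short (12-day) or long (25-day) study.

    With ``mean_matched=True`` every day keeps the same mixture mean and
    thermal mean; days differ only in spread and multimodality, which forces
    classifiers to rely on shape features (entropy, max−min).
    """
    if period not in ("short", "long"):
        raise ValidationError(f"period must be 'short' or 'long', got {period!r}")
    days = SHORT_DAYS if period == "short" else LONG_DAYS
    healthy = np.asarray(HEALTHY_REFLECTANCE)
    dry = np.asarray(DRY_REFLECTANCE)
    direction = dry - healthy
    specs = []
    for day in days:
        if mean_matched:
            s_scale, mults, weights, sp_scales = _MEAN_MATCHED[day]
            mean = healthy.copy()
            spread = s_scale * _base_sigma(mean)
            mults = np.asarray(mults, dtype=float)
            weights_arr = np.asarray(weights, dtype=float)
            mults = mults - float(mults @ weights_arr)  # exact zero mixture-mean shift
            offsets = np.outer(mults, spread)
            tir_mean, tir_std = 0.3, 0.1 + 0.08 * s_scale
            tir_offsets = mults * 0.0
        else:
            t, s_scale, t_offsets, weights, sp_scales = _TRAJECTORY[day]
            mean = (1 - t) * healthy + t * dry
            if day == 3:
                # active growth/bushing: slightly greener, stronger NIR
                mean = mean + np.array([0.0, 0.0, 0.012, 0.0, 0.0, 0.004, 0.02, 0.02])
            spread = s_scale * _base_sigma(mean)
            t_offsets = np.asarray(t_offsets, dtype=float)
            weights_arr = np.asarray(weights, dtype=float)
            # center so `mean`/`tir_mean` remain the exact mixture means
            t_offsets = t_offsets - float(t_offsets @ weights_arr)
            offsets = np.outer(t_offsets, direction)
            tir_mean, tir_std = _TIR_MEAN[day], _TIR_STD[day]
            tir_offsets = t_offsets * TIR_SUBPOP_DEGREES_PER_T
        specs.append(
            StateSpec(
                day=day,
                mean=mean,
                spread=spread,
                weights=np.asarray(weights, dtype=float),
                offsets=offsets,
                tir_mean=tir_mean,
                tir_std=tir_std,
                tir_offsets=tir_offsets,
                spread_scales=np.asarray(sp_scales, dtype=float),
            )
        )
    return specs


# ---------------------------------------------------------------------------
# Scene generation


def _plant_layout(config: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Spatially coherent plant blobs occupying ~plant_fraction of the raster."""
    field_ = rng.standard_normal((config.height, config.width))
    smooth = gaussian_filter(field_, sigma=max(min(config.height, config.width) / 16.0, 1.0))
    cut = np.quantile(smooth, 1.0 - config.plant_fraction)
    mask = smooth > cut
    if not mask.any():  # pathological tiny rasters
        mask.flat[int(np.argmax(smooth))] = True
    return mask


def generate_scene(config: SceneConfig, state: StateSpec, rng_seed: int | None = None) -> SyntheticScene:
    """One co-registered cube + thermal image + ground-truth plant mask."""
    n_bands = len(config.wavelengths)
    if len(state.mean) != n_bands:
        raise ValidationError(
            f"state has {len(state.mean)} bands, scene grid has {n_bands}"
        )
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed)]))

    mask = _plant_layout(config, rng)
    n_plant = int(mask.sum())
    cube = np.empty((config.height, config.width, n_bands))

    soil_mean = np.asarray(config.soil_reflectance, dtype=float)
    n_soil = mask.size - n_plant
    soil = soil_mean + rng.normal(0.0, config.soil_std, size=(n_soil, n_bands))

    comp = rng.choice(state.n_subpops, size=n_plant, p=state.weights)
    plant = (
        state.mean
        + state.offsets[comp]
        + rng.normal(0.0, 1.0, size=(n_plant, n_bands))
        * state.spread
        * state.spread_scales[comp, None]
    )

    cube[mask] = plant
    cube[~mask] = soil
    cube += rng.normal(0.0, config.noise_std, size=cube.shape)
    np.clip(cube, 0.0, None, out=cube)

    tir = np.empty((config.height, config.width))
    tir[mask] = (
        AMBIENT_TEMP_C
        + state.tir_mean
        + state.tir_offsets[comp]
        + rng.normal(0.0, state.tir_std, size=n_plant)
    )
    tir[~mask] = AMBIENT_TEMP_C + SOIL_TEMP_OFFSET_C + rng.normal(
        0.0, SOIL_TEMP_STD_C, size=n_soil
    )

    return SyntheticScene(
        cube=HyperCube(cube, np.asarray(config.wavelengths)),
        tir=GrayImage(tir, kind="TIR", name="TIR"),
        truth_mask=mask,
        day=state.day,
    )


def generate_experiment(
    config: SceneConfig, specs: list[StateSpec], seed: int = 0
) -> list[SyntheticScene]:
    """One scene per key-day spec, ordered by day, with per-scene seeds derived
    from the master seed as ``SeedSequence([seed, day])``."""
    if not specs:
        raise ValidationError("spec list is empty")
    scenes = []
    for spec in sorted(specs, key=lambda s: s.day):
        scene_seed = int(
            np.random.SeedSequence([int(seed), int(spec.day)]).generate_state(1)[0] % (2**31)
        )
        scenes.append(generate_scene(replace(config), spec, rng_seed=scene_seed))
    return scenes
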