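"""Synthetic hyperspectral ginkgo-leaf generator.

Emulates the statistical structure the downstream analysis assumes: a
fan-shaped leaf on a near-black cloth background, vegetation-like
reflectance curves for the green and yellow phenological stages, a
sex-linked reflectance offset (small and window-limited in the green stage,
larger and full-range in the yellow stage, male higher in both), a smooth
spatial texture field whose variance differs slightly between sexes (so the
image-feature battery also carries signal), and i.i.d. pixel noise.

Defaults encode the study conditions: delta_green = 0.01 reflectance on the
437-500 and 520-640 nm windows, delta_yellow = 0.03 across the full
437-998 nm window, background level 0.02, pixel noise sigma 0.01.
Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as _sk_polygon

from .hsi_io import HsiCube, WavelengthGrid, instrument_grid
from .leaf_spectra import BinaryMask

__all__ = [
    "GeneratorParams",
    "LabeledCube",
    "base_curve",
    "generate_leaf_cube",
    "generate_dataset",
    "PERIODS",
    "SEXES",
]

PERIODS = ("green", "yellow")
SEXES = ("male", "female")

GREEN_SEX_WINDOWS_NM = ((437.0, 500.0), (520.0, 640.0))
YELLOW_SEX_WINDOW_NM = (437.0, 998.0)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def base_curve(period: str, wavelengths: np.ndarray) -> np.ndarray:
    """Smooth stage-typical reflectance curve, clipped to [0, 1].

    Green: chlorophyll troughs in the blue and red, a green peak near
    550 nm, and a sigmoidal red edge near 715 nm rising to a NIR plateau.
    Yellow: carotenoid-dominated plateau from ~505 nm through the red,
    slightly higher NIR plateau.  Constants are fixed, documented choices.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if period == "green":
        r = (
            0.05
            + 0.10 * np.exp(-0.5 * ((wl - 550.0) / 30.0) ** 2)  # green peak
            + 0.40 * _logistic((wl - 715.0) / 15.0)  # red edge to NIR plateau
        )
    elif period == "yellow":
        r = (
            0.06
            + 0.30 * _logistic((wl - 505.0) / 18.0)  # yellow/red plateau
            + 0.12 * _logistic((wl - 715.0) / 20.0)  # NIR step
        )
    else:
        raise ValueError(f"unknown period '{period}'")
    return np.clip(r, 0.0, 1.0)


@dataclass(frozen=True)
class GeneratorParams:
    """Conditions of the synthetic study; defaults are the reference setup."""

    grid: WavelengthGrid = field(default_factory=instrument_grid)
    frame: tuple[int, int] = (64, 64)
    radius_range: tuple[float, float] = (21.0, 27.0)
    apex_angle_range_deg: tuple[float, float] = (120.0, 160.0)
    background: float = 0.02
    noise_sigma: float = 0.01
    band_noise_sigma: float = 0.002  # per-capture band calibration noise (constant over the frame)
    texture_smoothness: float = 3.0  # gaussian-filter sigma, px
    texture_amplitude: float = 0.02  # reflectance std of the smooth field
    texture_sex_contrast: float = 0.5  # male amplitude = (1 + contrast) * amplitude
    leaf_variability_sigma: float = 0.005  # std of the smooth per-leaf spectral deviation
    leaf_scale_jitter: float = 0.005  # relative std of per-leaf amplitude scaling
    trait_sigma: float = 0.0035  # per-leaf std along the period's sex-effect pattern
    delta_green: float = 0.01
    delta_yellow: float = 0.03
    green_windows: tuple[tuple[float, float], ...] = GREEN_SEX_WINDOWS_NM
    yellow_window: tuple[float, float] = YELLOW_SEX_WINDOW_NM

    def __post_init__(self) -> None:
        if self.delta_green < 0 or self.delta_yellow < 0:
            raise ValueError("sex effect sizes must be >= 0")
        if self.noise_sigma < 0 or self.texture_amplitude < 0:
            raise ValueError("noise and texture amplitudes must be >= 0")

    def null_sex_effect(self) -> "GeneratorParams":
        """A copy with every sex-linked parameter zeroed (the null condition)."""
        return replace(
            self, delta_green=0.0, delta_yellow=0.0, texture_sex_contrast=0.0
        )


@dataclass
class LabeledCube:
    """A synthetic observation with its ground truth."""

    cube: HsiCube
    truth_mask: BinaryMask
    period: str
    sex: str
    seed: int


def _effect_pattern(params: GeneratorParams, period: str) -> np.ndarray:
    """Unit indicator of the bands carrying the period's sex effect."""
    wl = params.grid.centers
    pattern = np.zeros_like(wl)
    if period == "green":
        for low, high in params.green_windows:
            pattern[(wl >= low) & (wl <= high)] = 1.0
    else:
        low, high = params.yellow_window
        pattern[(wl >= low) & (wl <= high)] = 1.0
    return pattern


def _sex_delta(params: GeneratorParams, period: str) -> float:
    return params.delta_green if period == "green" else params.delta_yellow


def _fan_mask(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Rasterized ginkgo-like circular sector with random pose and optional notch."""
    H, W = params.frame
    r = rng.uniform(*params.radius_range)
    apex_deg = rng.uniform(*params.apex_angle_range_deg)
    orient = rng.uniform(0.0, 2.0 * np.pi)
    half = np.deg2rad(apex_deg) / 2.0
    # apex sits opposite the fan so the sector straddles the frame center
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    ay = cy - 0.45 * r * np.sin(orient)
    ax = cx - 0.45 * r * np.cos(orient)
    arc = orient + np.linspace(-half, half, 40)
    ys = np.concatenate([[ay], ay + r * np.sin(arc)])
    xs = np.concatenate([[ax], ax + r * np.cos(arc)])
    if ys.min() < 0 or xs.min() < 0 or ys.max() > H - 1 or xs.max() > W - 1:
        raise ValueError(
            f"leaf (radius {r:.1f}) does not fit the {H}x{W} frame"
        )
    mask = np.zeros((H, W), dtype=bool)
    rr, cc = _sk_polygon(ys, xs, shape=(H, W))
    mask[rr, cc] = True
    if rng.random() < 0.5:  # central notch splitting the two lobes
        depth = rng.uniform(0.3, 0.6) * r
        notch_half = np.deg2rad(rng.uniform(2.0, 6.0))
        tip_y = ay + (r + 1.0) * np.sin(orient)
        tip_x = ax + (r + 1.0) * np.cos(orient)
        base = r + 1.0 - depth
        nys = [tip_y, ay + base * np.sin(orient - notch_half),
               ay + base * np.sin(orient + notch_half)]
        nxs = [tip_x, ax + base * np.cos(orient - notch_half),
               ax + base * np.cos(orient + notch_half)]
        rr, cc = _sk_polygon(np.clip(nys, 0, H - 1), np.clip(nxs, 0, W - 1),
                             shape=(H, W))
        mask[rr, cc] = False
    # same cleanup the segmenter applies: one connected silhouette, no
    # enclosed holes (removes rasterization crumbs along the notch)
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=range(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


def generate_leaf_cube(
    period: str, sex: str, params: GeneratorParams | None = None, seed: int = 0
) -> LabeledCube:
    """One labeled synthetic cube, deterministic per (period, sex, params, seed)."""
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}")
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    params = params or GeneratorParams()
    rng = np.random.default_rng(seed)
    H, W = params.frame
    B = params.grid.count

    mask = _fan_mask(params, rng)
    # Per-leaf biology, independent of sex: a smooth spectral deviation, an
    # overall amplitude jitter, and individual variation of the sex-linked
    # trait itself (drawn along the same effect pattern the sex offset uses,
    # so individual variation genuinely overlaps the class difference).
    deviation = ndimage.gaussian_filter1d(rng.standard_normal(B), 8.0)
    dstd = deviation.std()
    if dstd > 0:
        deviation = deviation / dstd * params.leaf_variability_sigma
    scale = 1.0 + params.leaf_scale_jitter * rng.standard_normal()
    trait = params.trait_sigma * rng.standard_normal()
    # per-capture band calibration noise: i.i.d. across bands, constant over
    # the frame, so it does NOT average out in the mean spectrum
    band_noise = params.band_noise_sigma * rng.standard_normal(B)
    pattern = _effect_pattern(params, period)
    spectrum = scale * base_curve(period, params.grid.centers) + deviation + band_noise
    spectrum = spectrum + (trait + (_sex_delta(params, period) if sex == "male" else 0.0)) * pattern

    # smooth spatial texture field, unit std over the frame, sex-contrasted amp
    field_raw = ndimage.gaussian_filter(
        rng.standard_normal((H, W)), params.texture_smoothness
    )
    std = field_raw.std()
    if std > 0:
        field_raw = field_raw / std
    amp = params.texture_amplitude * (
        1.0 + (params.texture_sex_contrast if sex == "male" else 0.0)
    )
    texture = amp * field_raw
    # pure spatial pattern: demean over the leaf so texture does not shift
    # the mean spectrum (no radiometric confound with the sex offset)
    texture = texture - texture[mask].mean()

    noise = rng.normal(0.0, params.noise_sigma, size=(H, W, B))
    data = np.where(
        mask[:, :, None],
        spectrum[None, None, :] + texture[:, :, None],
        params.background,
    )
    data = np.clip(data + noise, 0.0, 1.0).astype(np.float32)

    cube = HsiCube(
        data=data,
        grid=params.grid,
        meta={"period": period, "sex": sex, "seed": str(seed), "synthetic": "true"},
    )
    return LabeledCube(
        cube=cube, truth_mask=BinaryMask(mask), period=period, sex=sex, seed=seed
    )


def generate_dataset(
    n_per_class: int,
    params: GeneratorParams | None = None,
    seed: int = 0,
) -> tuple[list[LabeledCube], pd.DataFrame]:
    """4 * n_per_class cubes (each period x sex cell) plus a metadata table.

    Child seeds are drawn from a SeedSequence spawned off the master seed,
    so the whole dataset regenerates identically from (n_per_class, seed).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(4 * n_per_class) % (2**31)
    cubes: list[LabeledCube] = []
    rows = []
    k = 0
    for period in PERIODS:
        for sex in SEXES:
            for i in range(n_per_class):
                child = int(child_seeds[k])
                cubes.append(generate_leaf_cube(period, sex, params, seed=child))
                rows.append(
                    {"id": f"{period[0]}{sex[0]}{i:04d}", "period": period,
                     "sex": sex, "seed": child}
                )
                k += 1
    meta = pd.DataFrame(rows)
    assert meta["id"].is_unique
    return cubes, meta


def iter_dataset(
    n_per_class: int,
    params: GeneratorParams | None = None,
    seed: int = 0,
):
    """Memory-light variant of :func:`generate_dataset`: yields cubes one at
    a time with their metadata row (same seeds and ordering)."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    params = params or GeneratorParams()
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(4 * n_per_class) % (2**31)
    k = 0
    for period in PERIODS:
        for sex in SEXES:
            for i in range(n_per_class):
                child = int(child_seeds[k])
                row = {"id": f"{period[0]}{sex[0]}{i:04d}", "period": period,
                       "sex": sex, "seed": child}
                yield generate_leaf_cube(period, sex, params, seed=child), row
                k += 1
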