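"""Leaf segmentation and mean-spectrum extraction.

The leaf is imaged on near-black blotting cloth, so a single near-infrared
band (default: nearest to 800 nm, where the vegetation plateau gives maximal
contrast) thresholded with Otsu's method separates leaf from background.
The whole-leaf silhouette is the region of interest; its per-band mean is the
sample's spectrum, cropped to the 437--998 nm window where the detector is
quiet (210 bands on the instrument fixture grid).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .hsi_io import HsiCube, WavelengthGrid, nearest_band

__all__ = [
    "BinaryMask",
    "Spectrum",
    "segment_background",
    "segment_cube",
    "extract_mean_spectrum",
    "crop_spectrum",
    "DEFAULT_WINDOW_NM",
    "DEFAULT_SEGMENTATION_NM",
]

DEFAULT_WINDOW_NM = (437.0, 998.0)
DEFAULT_SEGMENTATION_NM = 800.0


@dataclass
class BinaryMask:
    """Boolean foreground mask over an image frame."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 2:
            raise ValueError("mask must be 2-D")
        self.pixels = p.astype(bool)

    @property
    def area(self) -> int:
        return int(self.pixels.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class Spectrum:
    """Per-band reflectance paired with its wavelength grid."""

    values: np.ndarray
    grid: WavelengthGrid

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("spectrum values must be 1-D")
        if v.size != self.grid.count:
            raise ValueError(
                f"spectrum has {v.size} values but grid has {self.grid.count} bands"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        self.values = v

    def __len__(self) -> int:
        return self.values.size

    def to_csv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            {"wavelength_nm": self.grid.centers, "reflectance": self.values}
        ).to_csv(path, index=False)
        return path


def segment_background(
    band_image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Threshold a single-band image into a leaf mask.

    Foreground = pixels strictly above the threshold (Otsu-derived when
    ``method='otsu'``); only the largest connected component is kept and its
    holes are filled.

    Raises ``ValueError`` ("no leaf found") when nothing survives.
    """
    img = np.asarray(band_image, dtype=float)
    if img.ndim != 2:
        raise ValueError("band image must be 2-D")
    if not np.all(np.isfinite(img)):
        raise ValueError("band image must be finite")
    if method == "otsu":
        if img.min() == img.max():
            raise ValueError("no leaf found: constant image")
        thr = float(threshold_otsu(img))
    elif method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires an explicit threshold")
        thr = float(threshold)
    else:
        raise ValueError(f"unknown segmentation method '{method}'")
    fg = img > thr
    if not fg.any():
        raise ValueError("no leaf found: empty foreground after thresholding")
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    fg = ndimage.binary_fill_holes(fg)
    return BinaryMask(fg)


def segment_cube(
    cube: HsiCube,
    band_nm: float = DEFAULT_SEGMENTATION_NM,
    method: str = "otsu",
    threshold: float | None = None,
) -> BinaryMask:
    """Segment a cube on the band nearest *band_nm* (default NIR, 800 nm)."""
    b = nearest_band(cube.grid, band_nm)
    return segment_background(cube.data[:, :, b], method=method, threshold=threshold)


def extract_mean_spectrum(cube: HsiCube, mask: BinaryMask) -> Spectrum:
    """Per-band arithmetic mean of reflectance over the foreground pixels."""
    if mask.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube frame {cube.data.shape[:2]}"
        )
    if mask.area < 1:
        raise ValueError("cannot average over an empty mask")
    values = cube.data[mask.pixels].mean(axis=0).astype(float)
    return Spectrum(values=values, grid=cube.grid)


def crop_spectrum(
    spectrum: Spectrum, window: tuple[float, float] = DEFAULT_WINDOW_NM
) -> Spectrum:
    """Keep bands whose centers fall in the closed window [low, high] nm."""
    low, high = float(window[0]), float(window[1])
    if not low < high:
        raise ValueError(f"window must satisfy low < high, got {window}")
    keep = (spectrum.grid.centers >= low) & (spectrum.grid.centers <= high)
    if not keep.any():
        raise ValueError(f"no bands fall inside window {window}")
    return Spectrum(
        values=spectrum.values[keep],
        grid=WavelengthGrid(spectrum.grid.centers[keep]),
    )
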