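"""Hyperspectral cube I/O and RGB synthesis.

Cubes are stored as an ENVI-style pair: a plain-text ``.hdr`` header and a
raw band-sequential (BSQ) binary with 32-bit float reflectance.  Band-center
wavelengths live under the standard ``wavelength`` header key.  A 231-channel
VNIR instrument grid (400--1000 nm) ships with the package; it pins the three
band centers used for RGB synthesis (700.37, 545.64, 439.75 nm) and contains
exactly 210 centers inside the 437--998 nm analysis window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HsiCube",
    "RgbImage",
    "instrument_grid",
    "read_envi_cube",
    "write_envi_cube",
    "nearest_band",
    "synthesize_rgb",
    "save_rgb_png",
]

RGB_TARGETS_NM = (700.0, 546.0, 439.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band-center wavelengths in nanometres."""

    centers: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.centers, dtype=float)
        if c.ndim != 1 or c.size < 1:
            raise ValueError("wavelength grid must be a nonempty 1-D sequence")
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            raise ValueError("wavelength centers must be finite and positive")
        if c.size > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("wavelength centers must be strictly increasing")
        object.__setattr__(self, "centers", c)

    @property
    def count(self) -> int:
        return int(self.centers.size)

    def __len__(self) -> int:
        return self.count


@dataclass
class HsiCube:
    """H x W x B reflectance cube with its wavelength grid and free-form metadata."""

    data: np.ndarray
    grid: WavelengthGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.data)
        if d.ndim != 3:
            raise ValueError(f"cube data must be H x W x B, got shape {d.shape}")
        if d.shape[2] != self.grid.count:
            raise ValueError(
                f"cube has {d.shape[2]} bands but grid declares {self.grid.count}"
            )
        if d.shape[0] < 1 or d.shape[1] < 1:
            raise ValueError("cube spatial dimensions must be >= 1")
        self.data = d

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class RgbImage:
    """H x W x 3 display image plus the cube band indices each channel came from."""

    pixels: np.ndarray
    source_bands: tuple[int, int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("RGB image must be H x W x 3")
        self.pixels = p


def instrument_grid() -> WavelengthGrid:
    """The packaged 231-channel VNIR fixture grid."""
    text = (
        resources.files("ginkgohsi").joinpath("data/instrument_grid.txt").read_text()
    )
    centers = [
        float(line)
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return WavelengthGrid(np.array(centers))


# --- ENVI-style header/BSQ persistence ------------------------------------

_DATA_TYPE = 4  # 32-bit float


def write_envi_cube(cube: HsiCube, path: str | Path) -> Path:
    """Write *cube* as ``path.hdr`` + ``path.img`` (BSQ, float32, little-endian).

    Returns the header path.  Round-trips bit-exactly at float32 precision.
    """
    path = Path(path)
    if path.suffix == ".hdr":
        path = path.with_suffix("")
    hdr, img = path.with_suffix(".hdr"), path.with_suffix(".img")
    h, w, b = cube.shape
    wl = ", ".join(f"{c:.6f}" for c in cube.grid.centers)
    lines = [
        "ENVI",
        "file type = ENVI Standard",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        f"data type = {_DATA_TYPE}",
        "interleave = bsq",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = { " + wl + " }",
    ]
    for key, val in cube.meta.items():
        if isinstance(val, str) and "\n" not in val:
            lines.append(f"{key} = {val}")
    hdr.write_text("\n".join(lines) + "\n")
    # BSQ: band-major on disk
    np.ascontiguousarray(
        np.transpose(cube.data, (2, 0, 1)).astype("<f4")
    ).tofile(img)
    return hdr


def _parse_envi_header(text: str) -> dict:
    """Parse 'key = value' pairs; brace-enclosed values may span lines."""
    fields: dict[str, str] = {}
    # collapse brace groups onto one line
    text = re.sub(
        r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text, flags=re.S
    )
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi_cube(header_path: str | Path) -> HsiCube:
    """Read an ENVI header + BSQ binary pair into an :class:`HsiCube`."""
    hdr = Path(header_path)
    if not hdr.exists():
        raise FileNotFoundError(f"header not found: {hdr}")
    fields = _parse_envi_header(hdr.read_text())
    for key in ("samples", "lines", "bands"):
        if key not in fields:
            raise ValueError(f"ENVI header missing required key '{key}'")
    if "wavelength" not in fields:
        raise ValueError("ENVI header missing required key 'wavelength'")
    w, h, b = (int(fields[k]) for k in ("samples", "lines", "bands"))
    wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
    centers = np.array([float(t) for t in wl_text.split(",") if t.strip()])
    if centers.size != b:
        raise ValueError(
            f"header declares {b} bands but lists {centers.size} wavelengths"
        )
    interleave = fields.get("interleave", "bsq").lower()
    if interleave != "bsq":
        raise ValueError(f"only BSQ interleave supported, got '{interleave}'")
    dtype = {1: "u1", 2: "<i2", 4: "<f4", 5: "<f8", 12: "<u2"}.get(
        int(fields.get("data type", _DATA_TYPE))
    )
    if dtype is None:
        raise ValueError(f"unsupported ENVI data type {fields.get('data type')}")
    img = hdr.with_suffix(".img")
    if not img.exists():
        raise FileNotFoundError(f"binary not found: {img}")
    raw = np.fromfile(img, dtype=dtype)
    if raw.size != h * w * b:
        raise ValueError(
            f"binary holds {raw.size} values; header implies {h * w * b} "
            f"({b} bands x {h} lines x {w} samples)"
        )
    data = raw.reshape(b, h, w).transpose(1, 2, 0).astype(np.float32)
    meta = {
        k: v
        for k, v in fields.items()
        if k
        not in {
            "samples", "lines", "bands", "wavelength", "interleave",
            "data type", "byte order", "header offset", "file type",
            "wavelength units",
        }
    }
    return HsiCube(data=data, grid=WavelengthGrid(centers), meta=meta)


# --- band selection and RGB synthesis --------------------------------------


def nearest_band(grid: WavelengthGrid, target_nm: float) -> int:
    """Index of the band center closest to *target_nm*; ties go to the lower index."""
    dist = np.abs(grid.centers - float(target_nm))
    return int(np.argmin(dist))  # argmin takes the first (lower) index on ties


def synthesize_rgb(
    cube: HsiCube, targets: tuple[float, float, float] = RGB_TARGETS_NM
) -> RgbImage:
    """Build a display RGB image from the cube bands nearest the target wavelengths.

    Each channel is min-max scaled to [0, 1] over the whole frame.  A channel
    whose selected band is constant is set to zeros and flagged in ``meta``.
    """
    if len(targets) != 3:
        raise ValueError("exactly three target wavelengths required (R, G, B)")
    bands = tuple(nearest_band(cube.grid, t) for t in targets)
    channels = []
    flat = []
    for b in bands:
        ch = cube.data[:, :, b].astype(float)
        lo, hi = float(ch.min()), float(ch.max())
        if hi > lo:
            channels.append((ch - lo) / (hi - lo))
            flat.append(False)
        else:
            channels.append(np.zeros_like(ch))
            flat.append(True)
    pixels = np.stack(channels, axis=-1)
    meta = {"target_nm": tuple(float(t) for t in targets)}
    if any(flat):
        meta["constant_channels"] = [i for i, f in enumerate(flat) if f]
    return RgbImage(pixels=pixels, source_bands=bands, meta=meta)


def save_rgb_png(rgb: RgbImage, path: str | Path) -> Path:
    """Export an :class:`RgbImage` as an 8-bit PNG."""
    import imageio.v3 as iio

    path = Path(path)
    px = np.clip(rgb.pixels, 0.0, 1.0)
    iio.imwrite(path, (px * 255).round().astype(np.uint8))
    return path
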