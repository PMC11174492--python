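"""The 53-variable image feature battery and spectral-image fusion.

Blocks (in order): color moments (6), GLCM Haralick statistics at four
angles (16), gray-gradient co-occurrence statistics (15), gray-level
difference statistics (4), Tamura perceptual texture (5), and Hu invariant
moments of the leaf silhouette (7).  Fusing the 210-band cropped mean
spectrum in front yields the 263-feature vector used by the fusion models.

Co-occurrence statistics are mask-aware: pixel pairs touching the background
are excluded, so the irregular leaf outline does not contaminate the counts.
Gray (and gradient) images are quantized to 16 levels by default over the
foreground min-max range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.measure import moments_hu, moments_normalized, moments_central

from .hsi_io import RgbImage
from .leaf_spectra import BinaryMask, Spectrum

__all__ = [
    "FeatureVector",
    "GrayImage",
    "to_gray",
    "color_moments",
    "glcm_features",
    "ggcm_features",
    "gldm_features",
    "tamura_features",
    "hu_moments",
    "extract_image_features",
    "fuse",
    "IMAGE_BLOCKS",
    "SPECTRAL_LENGTH",
    "IMAGE_LENGTH",
    "FUSION_LENGTH",
]

# block name -> length; concatenation order is fixed
IMAGE_BLOCKS = (
    ("color", 6),
    ("glcm", 16),
    ("ggcm", 15),
    ("gldm", 4),
    ("tamura", 5),
    ("hu", 7),
)
SPECTRAL_LENGTH = 210
IMAGE_LENGTH = sum(n for _, n in IMAGE_BLOCKS)  # 53
FUSION_LENGTH = SPECTRAL_LENGTH + IMAGE_LENGTH  # 263

GLCM_ANGLES = (0, 45, 90, 135)
# image-coordinate displacement (dy, dx) for each angle at distance 1
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

_GGCM_NAMES = (
    "small_gradient_dominance",
    "large_gradient_dominance",
    "gray_nonuniformity",
    "gradient_nonuniformity",
    "energy",
    "gray_mean",
    "gradient_mean",
    "gray_std",
    "gradient_std",
    "correlation",
    "gray_entropy",
    "gradient_entropy",
    "mixing_entropy",
    "inertia",
    "inverse_difference_moment",
)


@dataclass
class FeatureVector:
    """Ordered feature values with a named block layout.

    ``block_map`` maps block name -> (offset, length); blocks tile the vector
    without gaps.  ``names`` gives one identifier per entry.
    """

    values: np.ndarray
    block_map: dict[str, tuple[int, int]]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float).ravel()
        total = sum(n for _, n in self.block_map.values())
        if total != v.size:
            raise ValueError(
                f"block lengths sum to {total} but vector has {v.size} entries"
            )
        offsets = sorted(self.block_map.values())
        pos = 0
        for off, ln in offsets:
            if off != pos:
                raise ValueError("block_map offsets must tile the vector without gaps")
            pos = off + ln
        if self.names and len(self.names) != v.size:
            raise ValueError("names length must match values length")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must all be finite")
        self.values = v

    def block(self, name: str) -> np.ndarray:
        off, ln = self.block_map[name]
        return self.values[off : off + ln]

    def __len__(self) -> int:
        return self.values.size


@dataclass
class GrayImage:
    """Quantized gray image restricted to a foreground mask.

    ``pixels`` holds integer levels in [0, levels-1]; background entries are
    present but excluded from every statistic via ``mask``.
    """

    pixels: np.ndarray
    levels: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 gray levels")
        p = np.asarray(self.pixels)
        m = np.asarray(self.mask, dtype=bool)
        if p.shape != m.shape:
            raise ValueError("pixels and mask shapes differ")
        fg = p[m]
        if fg.size and (fg.min() < 0 or fg.max() > self.levels - 1):
            raise ValueError("quantized pixels outside [0, levels-1]")
        self.pixels = p.astype(np.intp)
        self.mask = m


def to_gray(rgb: RgbImage, mask: BinaryMask, levels: int = 16) -> GrayImage:
    """Rec.601 luminance quantized to ``levels`` bins over the foreground range."""
    px = np.asarray(rgb.pixels, dtype=float)
    if px.shape[:2] != mask.shape:
        raise ValueError("RGB frame and mask shapes differ")
    if mask.area < 1:
        raise ValueError("cannot build a gray image from an empty mask")
    lum = 0.299 * px[:, :, 0] + 0.587 * px[:, :, 1] + 0.114 * px[:, :, 2]
    fg = lum[mask.pixels]
    lo, hi = float(fg.min()), float(fg.max())
    if hi > lo:
        q = np.floor((lum - lo) / (hi - lo) * levels).astype(np.intp)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros_like(lum, dtype=np.intp)
    q[~mask.pixels] = 0
    return GrayImage(pixels=q, levels=levels, mask=mask.pixels)


def color_moments(rgb: RgbImage, mask: BinaryMask) -> np.ndarray:
    """(meanR, meanG, meanB, stdR, stdG, stdB) over foreground pixels.

    Standard deviations are population (ddof=0).
    """
    if mask.area < 1:
        raise ValueError("empty mask")
    px = np.asarray(rgb.pixels, dtype=float)
    if px.shape[:2] != mask.shape:
        raise ValueError("RGB frame and mask shapes differ")
    fg = px[mask.pixels]  # n x 3
    return np.concatenate([fg.mean(axis=0), fg.std(axis=0, ddof=0)])


# --- GLCM -------------------------------------------------------------------


def _cooccurrence(gray: GrayImage, offset: tuple[int, int]) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix at *offset*, foreground-only pairs.

    Returns an all-zero matrix when no valid pair exists at the offset.
    """
    g, m, L = gray.pixels, gray.mask, gray.levels
    dy, dx = offset
    H, W = g.shape
    ys = slice(max(0, -dy), min(H, H - dy))
    xs = slice(max(0, -dx), min(W, W - dx))
    ys2 = slice(max(0, dy), min(H, H + dy))
    xs2 = slice(max(0, dx), min(W, W + dx))
    a, b = g[ys, xs], g[ys2, xs2]
    valid = m[ys, xs] & m[ys2, xs2]
    if not valid.any():
        return np.zeros((L, L))
    i, j = a[valid].ravel(), b[valid].ravel()
    P = np.bincount(i * L + j, minlength=L * L).reshape(L, L).astype(float)
    P = P + P.T  # symmetric accumulation
    return P / P.sum()


def _glcm_stats(P: np.ndarray) -> tuple[float, float, float, float]:
    """(contrast, correlation, energy, homogeneity) of a normalized GLCM."""
    L = P.shape[0]
    i, j = np.meshgrid(np.arange(L), np.arange(L), indexing="ij")
    if P.sum() == 0:  # no valid pairs at this angle
        return 0.0, 0.0, 0.0, 0.0
    contrast = float((P * (i - j) ** 2).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    pi = P.sum(axis=1)
    mu = float((np.arange(L) * pi).sum())
    sigma2 = float(((np.arange(L) - mu) ** 2 * pi).sum())
    if sigma2 > 0:
        correlation = float(((i - mu) * (j - mu) * P).sum() / sigma2)
    else:
        correlation = 0.0  # constant-image convention
    return contrast, correlation, energy, homogeneity


def glcm_features(gray: GrayImage) -> np.ndarray:
    """16 Haralick statistics: (contrast, correlation, energy, homogeneity)
    at 0, 45, 90 and 135 degrees, distance 1, angle-major order."""
    out = []
    for ang in GLCM_ANGLES:
        P = _cooccurrence(gray, _ANGLE_OFFSETS[ang])
        if P.sum() == 0:
            import warnings

            warnings.warn(f"no valid pixel pairs at angle {ang}; features set to 0")
            out.extend([0.0, 0.0, 0.0, 0.0])
        else:
            out.extend(_glcm_stats(P))
    return np.array(out)


# --- GGCM -------------------------------------------------------------------

_SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)


def _entropy(p: np.ndarray) -> float:
    """Natural-log entropy with the 0*log0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def ggcm_features(gray: GrayImage, gradient_levels: int | None = None) -> np.ndarray:
    """15 gray-gradient co-occurrence statistics.

    Gradient magnitude comes from the 3x3 Sobel operator on the quantized
    gray image, quantized to ``gradient_levels`` bins (default: same as gray)
    over [0, max].  Only pixels whose 3x3 Sobel window lies entirely inside
    the foreground contribute.  Order follows ``_GGCM_NAMES``.
    """
    g, m, L = gray.pixels.astype(float), gray.mask, gray.levels
    Lg = gradient_levels or gray.levels
    inner = ndimage.binary_erosion(m, structure=np.ones((3, 3)))
    if not inner.any():
        raise ValueError("foreground too small for a 3x3 gradient window")
    gx = ndimage.convolve(g, _SOBEL_X, mode="nearest")
    gy = ndimage.convolve(g, _SOBEL_X.T, mode="nearest")
    mag = np.sqrt(gx**2 + gy**2)
    gm = mag[inner]
    hi = float(gm.max())
    if hi > 0:
        q = np.clip(np.floor(mag / hi * Lg), 0, Lg - 1).astype(np.intp)
    else:
        q = np.zeros_like(mag, dtype=np.intp)
    gi = gray.pixels[inner].ravel()
    gj = q[inner].ravel()
    Hm = np.bincount(gi * Lg + gj, minlength=L * Lg).reshape(L, Lg).astype(float)
    p = Hm / Hm.sum()

    i = np.arange(L)[:, None]
    j = np.arange(Lg)[None, :]
    p_gray = p.sum(axis=1)
    p_grad = p.sum(axis=0)
    mu_g = float((np.arange(L) * p_gray).sum())
    mu_d = float((np.arange(Lg) * p_grad).sum())
    var_g = float(((np.arange(L) - mu_g) ** 2 * p_gray).sum())
    var_d = float(((np.arange(Lg) - mu_d) ** 2 * p_grad).sum())
    if var_g > 0 and var_d > 0:
        corr = float(
            ((i - mu_g) * (j - mu_d) * p).sum() / np.sqrt(var_g * var_d)
        )
    else:
        corr = 0.0
    feats = {
        "small_gradient_dominance": float((p / (j + 1.0) ** 2).sum()),
        "large_gradient_dominance": float((p * j.astype(float) ** 2).sum()),
        "gray_nonuniformity": float((p_gray**2).sum()),
        "gradient_nonuniformity": float((p_grad**2).sum()),
        "energy": float((p**2).sum()),
        "gray_mean": mu_g,
        "gradient_mean": mu_d,
        "gray_std": float(np.sqrt(var_g)),
        "gradient_std": float(np.sqrt(var_d)),
        "correlation": corr,
        "gray_entropy": _entropy(p_gray),
        "gradient_entropy": _entropy(p_grad),
        "mixing_entropy": _entropy(p.ravel()),
        "inertia": float((p * (i - j) ** 2).sum()),
        "inverse_difference_moment": float((p / (1.0 + (i - j) ** 2)).sum()),
    }
    return np.array([feats[name] for name in _GGCM_NAMES])


# --- GLDM -------------------------------------------------------------------


def gldm_features(
    gray: GrayImage, displacement: tuple[int, int] = (0, 1)
) -> np.ndarray:
    """4 gray-level difference statistics at one displacement.

    Normalized histogram P(d) of absolute gray differences over
    foreground-only pairs; returns (mean, contrast, angular second moment,
    entropy).
    """
    g, m, L = gray.pixels, gray.mask, gray.levels
    dy, dx = displacement
    H, W = g.shape
    ys = slice(max(0, -dy), min(H, H - dy))
    xs = slice(max(0, -dx), min(W, W - dx))
    ys2 = slice(max(0, dy), min(H, H + dy))
    xs2 = slice(max(0, dx), min(W, W + dx))
    a, b = g[ys, xs], g[ys2, xs2]
    valid = m[ys, xs] & m[ys2, xs2]
    if not valid.any():
        raise ValueError(f"no valid pixel pairs at displacement {displacement}")
    d = np.abs(a[valid].astype(int) - b[valid].astype(int)).ravel()
    P = np.bincount(d, minlength=L).astype(float)
    P /= P.sum()
    dvals = np.arange(P.size, dtype=float)
    return np.array(
        [
            float((dvals * P).sum()),
            float((dvals**2 * P).sum()),
            float((P**2).sum()),
            _entropy(P),
        ]
    )


# --- Tamura -----------------------------------------------------------------


def _tamura_coarseness(g: np.ndarray, mask: np.ndarray, kmax: int) -> float:
    """Mean best window size 2^k over foreground pixels (Tamura coarseness)."""
    H, W = g.shape
    # average over 2^k x 2^k neighborhoods via integral image
    integral = np.zeros((H + 1, W + 1))
    integral[1:, 1:] = np.cumsum(np.cumsum(g, axis=0), axis=1)
    best_E = np.full((H, W), -1.0)
    best_S = np.ones((H, W))
    for k in range(kmax + 1):
        s = 2**k
        A = np.full((H, W), np.nan)
        # A[y, x] = mean over window [y-s//2 ... ), standard centered average
        ys, xs = np.arange(H), np.arange(W)
        y0 = ys - s // 2
        x0 = xs - s // 2
        oky = (y0 >= 0) & (y0 + s <= H)
        okx = (x0 >= 0) & (x0 + s <= W)
        yv, xv = np.ix_(ys[oky], xs[okx])
        y0v, x0v = np.ix_(y0[oky], x0[okx])
        A[yv, xv] = (
            integral[y0v + s, x0v + s]
            - integral[y0v, x0v + s]
            - integral[y0v + s, x0v]
            + integral[y0v, x0v]
        ) / (s * s)
        # horizontal / vertical differences of window averages at distance s
        Eh = np.full((H, W), np.nan)
        Ev = np.full((H, W), np.nan)
        if W > s:
            Eh[:, : W - s] = np.abs(A[:, s:] - A[:, :-s])
        if H > s:
            Ev[: H - s, :] = np.abs(A[s:, :] - A[:-s, :])
        E = np.fmax(np.nan_to_num(Eh, nan=-np.inf), np.nan_to_num(Ev, nan=-np.inf))
        upd = E > best_E
        best_E[upd] = E[upd]
        best_S[upd] = s
    vals = best_S[mask & (best_E > -np.inf)]
    if vals.size == 0:
        return 1.0
    return float(vals.mean())


def _tamura_contrast(fg: np.ndarray) -> float:
    """sigma / kurtosis^(1/4); 0 for a constant patch."""
    mu = fg.mean()
    sigma2 = ((fg - mu) ** 2).mean()
    if sigma2 == 0:
        return 0.0
    mu4 = ((fg - mu) ** 4).mean()
    kurt = mu4 / sigma2**2
    return float(np.sqrt(sigma2) / kurt**0.25)


_PREWITT_X = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)

_N_DIR_BINS = 16
_GRAD_FLOOR_FRAC = 12.0 / 255.0  # fraction of gray dynamic range


def _direction_field(
    gray: GrayImage,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel quantized edge direction (bin in [0, 16)) and validity mask.

    Directions are Prewitt-based, folded to [0, pi); pixels below the
    magnitude floor or whose 3x3 window touches background are invalid.
    """
    g, m = gray.pixels.astype(float), gray.mask
    inner = ndimage.binary_erosion(m, structure=np.ones((3, 3)))
    dx = ndimage.convolve(g, _PREWITT_X, mode="nearest") / 3.0
    dy = ndimage.convolve(g, _PREWITT_X.T, mode="nearest") / 3.0
    mag = (np.abs(dx) + np.abs(dy)) / 2.0
    floor = _GRAD_FLOOR_FRAC * (gray.levels - 1)
    valid = inner & (mag >= floor)
    theta = np.mod(np.arctan2(dy, dx), np.pi)  # fold to [0, pi)
    bins = np.clip(
        np.floor(theta / np.pi * _N_DIR_BINS).astype(int), 0, _N_DIR_BINS - 1
    )
    return bins, valid


def _tamura_directionality(bins: np.ndarray, valid: np.ndarray) -> float:
    """Single-peak sharpness of the direction histogram, in [0, 1]."""
    if not valid.any():
        return 0.0
    HD = np.bincount(bins[valid].ravel(), minlength=_N_DIR_BINS).astype(float)
    HD /= HD.sum()
    peak = int(np.argmax(HD))
    centers = (np.arange(_N_DIR_BINS) + 0.5) * np.pi / _N_DIR_BINS
    d = np.abs(centers - centers[peak])
    d = np.minimum(d, np.pi - d)  # wrapped angular distance, max pi/2
    second_moment = float((HD * d**2).sum())
    return float(np.clip(1.0 - second_moment / (np.pi / 2) ** 2 * 4.0, 0.0, 1.0))


def _tamura_linearity(
    bins: np.ndarray, valid: np.ndarray, distance: int = 4
) -> float:
    """Direction co-occurrence concentration along the diagonal (line-likeness)."""
    n = _N_DIR_BINS
    total = 0.0
    weighted = 0.0
    for dy, dx in ((0, distance), (distance, 0), (distance, distance),
                   (distance, -distance)):
        H, W = bins.shape
        ys = slice(max(0, -dy), min(H, H - dy))
        xs = slice(max(0, -dx), min(W, W - dx))
        ys2 = slice(max(0, dy), min(H, H + dy))
        xs2 = slice(max(0, dx), min(W, W + dx))
        a, b = bins[ys, xs], bins[ys2, xs2]
        ok = valid[ys, xs] & valid[ys2, xs2]
        if not ok.any():
            continue
        diff = a[ok] - b[ok]
        weighted += float(np.cos(diff * (2.0 * np.pi / n)).sum())
        total += float(ok.sum())
    if total == 0:
        return 0.0
    return weighted / total


def tamura_features(gray: GrayImage) -> np.ndarray:
    """(coarseness, contrast, directionality, linearity, roughness).

    Roughness is defined as coarseness + contrast.  Works on small images
    (the coarseness window cap shrinks with the frame); 32x32 foreground or
    larger is recommended.
    """
    g, m = gray.pixels.astype(float), gray.mask
    if not m.any():
        raise ValueError("empty mask")
    H, W = g.shape
    kmax = max(0, min(5, int(np.floor(np.log2(min(H, W)))) - 1))
    coarseness = _tamura_coarseness(g, m, kmax)
    contrast = _tamura_contrast(g[m])
    bins, valid = _direction_field(gray)
    directionality = _tamura_directionality(bins, valid)
    linearity = _tamura_linearity(bins, valid)
    roughness = coarseness + contrast
    return np.array([coarseness, contrast, directionality, linearity, roughness])


# --- Hu moments -------------------------------------------------------------


def hu_moments(mask: BinaryMask) -> np.ndarray:
    """The 7 Hu invariants of the binary silhouette (shape feature)."""
    if mask.area < 1:
        raise ValueError("empty mask")
    img = mask.pixels.astype(float)
    mu = moments_central(img)
    nu = moments_normalized(mu)
    return moments_hu(nu)


# --- assembly ---------------------------------------------------------------


def _block_names() -> list[str]:
    names = [f"color_{c}" for c in ("mean_r", "mean_g", "mean_b", "std_r", "std_g", "std_b")]
    for ang in GLCM_ANGLES:
        names += [f"glcm_{s}_{ang}" for s in ("contrast", "correlation", "energy", "homogeneity")]
    names += [f"ggcm_{n}" for n in _GGCM_NAMES]
    names += [f"gldm_{s}" for s in ("mean", "contrast", "asm", "entropy")]
    names += [f"tamura_{s}" for s in ("coarseness", "contrast", "directionality", "linearity", "roughness")]
    names += [f"hu_phi{k}" for k in range(1, 8)]
    return names


def extract_image_features(
    rgb: RgbImage, mask: BinaryMask, levels: int = 16
) -> FeatureVector:
    """Concatenate all 53 image features: color | glcm | ggcm | gldm | tamura | hu."""
    gray = to_gray(rgb, mask, levels=levels)
    parts = [
        color_moments(rgb, mask),
        glcm_features(gray),
        ggcm_features(gray),
        gldm_features(gray),
        tamura_features(gray),
        hu_moments(mask),
    ]
    values = np.concatenate(parts)
    block_map: dict[str, tuple[int, int]] = {}
    off = 0
    for (name, ln), part in zip(IMAGE_BLOCKS, parts):
        if part.size != ln:
            raise RuntimeError(f"block '{name}' produced {part.size} values, expected {ln}")
        block_map[name] = (off, ln)
        off += ln
    return FeatureVector(values=values, block_map=block_map, names=_block_names())


def fuse(spectrum: Spectrum, image_features: FeatureVector) -> FeatureVector:
    """Spectral-first concatenation: 210 spectral + 53 image = 263 features."""
    if len(spectrum) != SPECTRAL_LENGTH:
        raise ValueError(
            f"spectral block must have {SPECTRAL_LENGTH} bands, got {len(spectrum)}"
        )
    if len(image_features) != IMAGE_LENGTH:
        raise ValueError(
            f"image block must have {IMAGE_LENGTH} features, got {len(image_features)}"
        )
    values = np.concatenate([spectrum.values, image_features.values])
    block_map = {"spectral": (0, SPECTRAL_LENGTH)}
    for name, (off, ln) in image_features.block_map.items():
        block_map[name] = (off + SPECTRAL_LENGTH, ln)
    names = [f"refl_{w:.2f}nm" for w in spectrum.grid.centers] + list(
        image_features.names
    )
    return FeatureVector(values=values, block_map=block_map, names=names)
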