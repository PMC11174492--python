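"""Square-image preprocessing for RGB leaf photographs.

Three modes: proportional scaling with black background expansion
(``scale_pad``, the recommended transform), direct anisotropic resizing
(``direct_resize``), and padding without rescaling (``pad_only``).  The
default side length is 560 px.  Content is centered; padding pixels are
exactly black.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["SquareImage", "scale_pad", "direct_resize", "pad_only", "DEFAULT_SIDE"]

DEFAULT_SIDE = 560


@dataclass
class SquareImage:
    """S x S x 3 image with its construction mode and content placement."""

    pixels: np.ndarray
    side: int
    mode: str
    placement: tuple[int, int]  # top-left (row, col) of the embedded content

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise ValueError("square image must be S x S x 3")
        if p.shape[0] != self.side or p.shape[1] != self.side:
            raise ValueError("pixel array does not match declared side length")
        self.pixels = p


def _check_side(side: int) -> None:
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")


def _as_rgb(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("input image must be H x W x 3 (or 2-D grayscale)")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("input image must be at least 1 x 1")
    return img


def _embed(content: np.ndarray, side: int, mode: str) -> SquareImage:
    """Center *content* in a black side x side frame (extra pixel to bottom/right)."""
    h, w = content.shape[:2]
    out = np.zeros((side, side, 3), dtype=content.dtype)
    r0 = (side - h) // 2
    c0 = (side - w) // 2
    out[r0 : r0 + h, c0 : c0 + w] = content
    return SquareImage(pixels=out, side=side, mode=mode, placement=(r0, c0))


def scale_pad(image: np.ndarray, side: int = DEFAULT_SIDE) -> SquareImage:
    """Aspect-preserving resize so the long side equals *side*, then pad black."""
    _check_side(side)
    img = _as_rgb(image)
    h, w = img.shape[:2]
    scale = side / max(h, w)
    nh = max(1, round(h * scale))
    nw = max(1, round(w * scale))
    # keep the long side exact after rounding
    if h >= w:
        nh = side
    else:
        nw = side
    if (nh, nw) != (h, w):
        content = _sk_resize(img, (nh, nw), order=1, anti_aliasing=False,
                             preserve_range=True)
    else:
        content = img.copy()
    return _embed(content, side, "scale_pad")


def direct_resize(image: np.ndarray, side: int = DEFAULT_SIDE) -> SquareImage:
    """Non-aspect-preserving resize straight to side x side (no padding)."""
    _check_side(side)
    img = _as_rgb(image)
    if img.shape[:2] != (side, side):
        content = _sk_resize(img, (side, side), order=1, anti_aliasing=False,
                             preserve_range=True)
    else:
        content = img.copy()
    return SquareImage(pixels=content, side=side, mode="direct_resize",
                       placement=(0, 0))


def pad_only(image: np.ndarray, side: int = DEFAULT_SIDE) -> SquareImage:
    """Embed the image unscaled and centered in a black side x side frame."""
    _check_side(side)
    img = _as_rgb(image)
    h, w = img.shape[:2]
    if h > side or w > side:
        raise ValueError(
            f"content {h}x{w} exceeds frame side {side}; pad_only does not crop"
        )
    return _embed(img, side, "pad_only")
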