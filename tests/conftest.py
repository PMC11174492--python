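import numpy as np
import pytest

from ginkgohsi.hsi_io import HsiCube, RgbImage, WavelengthGrid, instrument_grid
from ginkgohsi.leaf_spectra import BinaryMask
from ginkgohsi.synthetic_leaves import generate_leaf_cube


@pytest.fixture(scope="session")
def fixture_grid() -> WavelengthGrid:
    return instrument_grid()


@pytest.fixture(scope="session")
def green_leaf():
    """One deterministic synthetic green male leaf."""
    return generate_leaf_cube("green", "male", seed=7)


@pytest.fixture(scope="session")
def yellow_leaf():
    return generate_leaf_cube("yellow", "female", seed=8)


@pytest.fixture()
def small_cube(fixture_grid) -> HsiCube:
    """4 x 4 x 231 random reflectance cube on the instrument grid."""
    rng = np.random.default_rng(123)
    data = rng.uniform(0.0, 1.0, size=(4, 4, fixture_grid.count)).astype(np.float32)
    return HsiCube(data=data, grid=fixture_grid, meta={"note": "test cube"})


def random_gray(seed: int, max_side: int = 8, max_levels: int = 8):
    """A random small quantized image + full-frame mask for oracle checks."""
    rng = np.random.default_rng(seed)
    h = rng.integers(3, max_side + 1)
    w = rng.integers(3, max_side + 1)
    levels = int(rng.integers(2, max_levels + 1))
    img = rng.integers(0, levels, size=(h, w))
    mask = np.ones((h, w), dtype=bool)
    if rng.random() < 0.5:  # sometimes knock out a few pixels (irregular mask)
        knock = rng.random(size=(h, w)) < 0.15
        mask &= ~knock
        # keep a 3x3 interior so GGCM stays defined
        mask[h // 2 - 1 : h // 2 + 2, w // 2 - 1 : w // 2 + 2] = True
    return img, mask, levels


def as_rgb(arr: np.ndarray) -> RgbImage:
    """Wrap a 2-D array as a flat-gray RgbImage (R=G=B)."""
    return RgbImage(pixels=np.stack([arr] * 3, axis=-1), source_bands=(0, 1, 2))


def full_mask(shape) -> BinaryMask:
    return BinaryMask(np.ones(shape, dtype=bool))
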