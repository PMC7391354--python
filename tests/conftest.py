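from __future__ import annotations

import numpy as np
import pytest

from radstab.grids import BinaryMask, ImageGrid
from radstab.preprocess import DiscretizedROI


def make_roi(levels: np.ndarray,
             spacing: tuple[float, float] = (1.0, 1.0)) -> DiscretizedROI:
    """DiscretizedROI straight from a level array (0 = outside mask)."""
    levels = np.asarray(levels, dtype=np.int64)
    mask = levels > 0
    return DiscretizedROI(levels=levels, mask=mask,
                          raw=levels[mask].astype(np.float64),
                          ng=int(levels.max()), spacing=spacing)


def random_roi(rng: np.random.Generator, size: int = 8,
               ng: int = 4, p_mask: float = 0.85) -> DiscretizedROI:
    """Random small ROI with partial mask coverage for oracle comparisons."""
    levels = rng.integers(1, ng + 1, size=(size, size))
    mask = rng.random((size, size)) < p_mask
    if not mask.any():
        mask[size // 2, size // 2] = True
    levels = np.where(mask, levels, 0)
    return make_roi(levels)


@pytest.fixture
def disc_mask() -> BinaryMask:
    """Rasterised disc of radius 10 mm at 1 mm spacing."""
    n = 32
    r, c = np.mgrid[0:n, 0:n]
    centre = (n - 1) / 2
    return BinaryMask(np.hypot(r - centre, c - centre) <= 10.0)


@pytest.fixture
def square_image_mask() -> tuple[ImageGrid, BinaryMask]:
    """Flat 40x40 image with a 10x10 lesion of distinct intensity."""
    img = np.full((40, 40), -800.0)
    msk = np.zeros((40, 40), dtype=bool)
    msk[15:25, 15:25] = True
    img[msk] = 40.0
    return ImageGrid(img), BinaryMask(msk)
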