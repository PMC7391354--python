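"""Image conditioning ahead of feature extraction.

Covers isotropic resampling, lesion-centred cropping, organ masking,
principal-slice selection, the lesion eligibility filter (minimum volume,
single connected component) and fixed-bin-width intensity discretization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label

from .grids import BinaryMask, ImageGrid

__all__ = [
    "PreprocessConfig", "DiscretizedROI", "EligibilityResult",
    "resample", "crop_roi", "apply_organ_mask", "select_principal_slice",
    "eligibility_filter", "min_sphere_radius", "discretize",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Protocol constants of the extraction pipeline.

    target_spacing_mm : isotropic pixel spacing after resampling (1 mm).
    bin_width_hu      : fixed bin width for gray-level discretization (25 HU).
    crop_size_px      : side length of the lesion-centred crop
                        (128 for lung, 192 for abdominal CT).
    min_volume_mm3    : smallest lesion volume considered (30 mm^3).
    slice_thickness_mm: extrusion thickness giving the 2D slice its volume
                        semantics (defaults to the resampled 1 mm).
    organ_mask_fill_hu: HU written outside an organ mask (-1000, air).
    """

    target_spacing_mm: float = 1.0
    bin_width_hu: float = 25.0
    crop_size_px: int = 128
    min_volume_mm3: float = 30.0
    slice_thickness_mm: float = 1.0
    organ_mask_fill_hu: float = -1000.0

    def __post_init__(self) -> None:
        if self.target_spacing_mm <= 0:
            raise ValueError("target_spacing_mm must be positive")
        if self.bin_width_hu <= 0:
            raise ValueError("bin_width_hu must be positive")
        if self.min_volume_mm3 < 0:
            raise ValueError("min_volume_mm3 must be non-negative")


@dataclass(frozen=True)
class DiscretizedROI:
    """Gray-level labelled ROI: substrate for all texture matrices.

    levels : 2D int array, 1..ng inside the mask, 0 outside.
    mask   : the ROI extent.
    raw    : original in-mask HU values (row-major order).
    ng     : highest occupied gray level.
    """

    levels: np.ndarray
    mask: np.ndarray
    raw: np.ndarray
    ng: int
    spacing: tuple[float, float]

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask]


@dataclass(frozen=True)
class EligibilityResult:
    accepted: bool
    reason: str
    n_components: int
    volume_mm3: float

    def __bool__(self) -> bool:
        return self.accepted


def resample(image: ImageGrid, mask: BinaryMask,
             target_spacing: float) -> tuple[ImageGrid, BinaryMask]:
    """Resample image (linear) and mask (nearest) to an isotropic lattice.

    A no-op when the input spacing already equals the target.
    """
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if image.spacing != mask.spacing or image.shape != mask.shape:
        raise ValueError("image and mask must share geometry")
    if image.spacing == (target_spacing, target_spacing):
        return image, mask
    factors = (image.spacing[0] / target_spacing,
               image.spacing[1] / target_spacing)
    out_img = ndimage.zoom(image.values, factors, order=1, mode="nearest",
                           grid_mode=True)
    out_msk = ndimage.zoom(mask.values.astype(np.uint8), factors, order=0,
                           mode="nearest", grid_mode=True)
    sp = (target_spacing, target_spacing)
    return ImageGrid(out_img, sp), BinaryMask(out_msk > 0, sp)


def _bbox_centre(mask: np.ndarray) -> tuple[int, int]:
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    # midpoint of the minimal enclosing rectangle; ties toward the lower index
    return (rows[0] + rows[-1]) // 2, (cols[0] + cols[-1]) // 2


def crop_roi(image: ImageGrid, mask: BinaryMask,
             crop_size: int) -> tuple[ImageGrid, BinaryMask]:
    """Crop a crop_size x crop_size window centred on the lesion.

    The lesion centre is the centre of the minimal rectangle covering the
    whole lesion. Windows extending past the image bounds are padded with
    the image minimum (background) / False.
    """
    if mask.is_empty():
        raise ValueError("cannot crop around an empty mask")
    rows = np.flatnonzero(mask.values.any(axis=1))
    cols = np.flatnonzero(mask.values.any(axis=0))
    if (rows[-1] - rows[0] + 1) > crop_size or (cols[-1] - cols[0] + 1) > crop_size:
        raise ValueError("crop_size smaller than the lesion bounding box")
    cr, cc = _bbox_centre(mask.values)
    r0 = cr - crop_size // 2
    c0 = cc - crop_size // 2
    fill = float(image.values.min())
    img_out = np.full((crop_size, crop_size), fill, dtype=np.float64)
    msk_out = np.zeros((crop_size, crop_size), dtype=bool)
    h, w = image.shape
    rs, re = max(r0, 0), min(r0 + crop_size, h)
    cs, ce = max(c0, 0), min(c0 + crop_size, w)
    img_out[rs - r0:re - r0, cs - c0:ce - c0] = image.values[rs:re, cs:ce]
    msk_out[rs - r0:re - r0, cs - c0:ce - c0] = mask.values[rs:re, cs:ce]
    return ImageGrid(img_out, image.spacing), BinaryMask(msk_out, mask.spacing)


def apply_organ_mask(image: ImageGrid, organ: BinaryMask,
                     fill: float = -1000.0) -> ImageGrid:
    """Set pixels outside the organ mask to `fill` HU."""
    if image.shape != organ.shape:
        raise ValueError(f"shape mismatch: {image.shape} vs {organ.shape}")
    out = image.values.copy()
    out[~organ.values] = fill
    return ImageGrid(out, image.spacing)


def select_principal_slice(mask3d: np.ndarray) -> int:
    """Index of the slice (axis 0) with the largest segmented area.

    Ties break toward the lowest index; an all-empty stack is an error.
    """
    areas = np.asarray(mask3d).astype(bool).sum(axis=(1, 2))
    if areas.sum() == 0:
        raise ValueError("all slices are empty")
    return int(np.argmax(areas))


def eligibility_filter(mask: BinaryMask, slice_thickness: float = 1.0,
                       min_volume: float = 30.0) -> EligibilityResult:
    """Lesion inclusion rule: single connected component and minimum volume.

    The slice is treated as a one-voxel-thick extrusion, so
    volume = area * spacing^2 * slice_thickness; lesions under `min_volume`
    mm^3 or split into several 8-connected fragments are rejected.
    """
    if mask.is_empty():
        return EligibilityResult(False, "empty mask", 0, 0.0)
    n_comp = int(label(mask.values, connectivity=2).max())
    volume = mask.area_mm2 * slice_thickness
    if n_comp > 1:
        return EligibilityResult(
            False, f"{n_comp} distinct components", n_comp, volume)
    if volume < min_volume:
        return EligibilityResult(
            False, f"volume {volume:.1f} mm^3 < {min_volume} mm^3",
            n_comp, volume)
    return EligibilityResult(True, "accepted", n_comp, volume)


def min_sphere_radius(volume: float) -> float:
    """Radius in mm of a sphere with the given volume in mm^3."""
    if volume <= 0:
        raise ValueError("volume must be positive")
    return (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)


def discretize(image: ImageGrid, mask: BinaryMask,
               bin_width: float = 25.0) -> DiscretizedROI:
    """Fixed-bin-width gray-level discretization anchored at the ROI minimum.

    level(x) = floor((x - min_in_mask) / bin_width) + 1, so a constant ROI
    maps to the single level 1 and levels are invariant to adding a constant
    to every in-mask intensity.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if image.shape != mask.shape:
        raise ValueError("image and mask must share shape")
    if mask.is_empty():
        raise ValueError("cannot discretize an empty ROI")
    m = mask.values
    raw = image.values[m]
    lvl = np.floor((image.values - raw.min()) / bin_width).astype(np.int64) + 1
    levels = np.where(m, lvl, 0)
    return DiscretizedROI(levels=levels, mask=m, raw=raw,
                          ng=int(levels.max()), spacing=image.spacing)
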