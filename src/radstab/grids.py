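"""Core raster containers: CT image grids and binary masks with physical spacing.

Images carry Hounsfield-unit intensities on a 2D lattice with per-axis pixel
spacing in millimetres; masks are boolean rasters aligned to the same lattice.
Both round-trip through NIfTI so cohorts can be exchanged with external tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["ImageGrid", "BinaryMask", "load_nifti_image", "load_nifti_mask",
           "save_nifti"]


@dataclass(frozen=True)
class ImageGrid:
    """2D scalar field of CT intensities (HU) with per-axis spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"ImageGrid must be 2D, got ndim={arr.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel in mm^2."""
        return self.spacing[0] * self.spacing[1]


@dataclass(frozen=True)
class BinaryMask:
    """2D boolean field aligned to an ImageGrid: one rater's lesion extent."""

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2:
            raise ValueError(f"BinaryMask must be 2D, got ndim={arr.ndim}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "values", arr.astype(bool))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area_px(self) -> int:
        return int(self.values.sum())

    @property
    def area_mm2(self) -> float:
        return self.area_px * self.spacing[0] * self.spacing[1]

    def is_empty(self) -> bool:
        return not self.values.any()


def _affine_from_spacing(spacing: tuple[float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = spacing[0]
    aff[1, 1] = spacing[1]
    return aff


def save_nifti(obj: ImageGrid | BinaryMask, path: str | Path) -> None:
    """Write a grid or mask as a single-slice NIfTI with spacing in the header."""
    data = obj.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data[..., np.newaxis], _affine_from_spacing(obj.spacing))
    img.header.set_zooms((obj.spacing[0], obj.spacing[1], 1.0))
    nib.save(img, str(path))


def _load(path: str | Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"{path}: expected a single-slice volume, "
                             f"got shape {data.shape}")
        data = data[..., 0]
    elif data.ndim != 2:
        raise ValueError(f"{path}: expected 2D or single-slice 3D data")
    zooms = img.header.get_zooms()[:2]
    return data, (float(zooms[0]), float(zooms[1]))


def load_nifti_image(path: str | Path) -> ImageGrid:
    data, spacing = _load(path)
    return ImageGrid(data.astype(np.float64), spacing)


def load_nifti_mask(path: str | Path) -> BinaryMask:
    data, spacing = _load(path)
    return BinaryMask(data > 0.5, spacing)
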