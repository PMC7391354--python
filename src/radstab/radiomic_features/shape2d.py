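"""Shape features of a single-slice lesion mask: 12 values.

A 2D axial slice is given volume semantics by extruding it one slice
thickness (default 1 mm, matching the isotropic resampling), so volumetric
descriptors (MeshVolume, SurfaceArea, Sphericity, ...) refer to the
one-voxel-thick solid. In-plane quantities (Perimeter, axis lengths,
Maximum2DDiameterSlice) are genuine 2D measurements.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from skimage.measure import find_contours, label

from ..grids import BinaryMask

__all__ = ["shape_features", "SHAPE_NAMES"]

SHAPE_NAMES = (
    "MeshVolume", "VoxelVolume", "SurfaceArea", "SurfaceVolumeRatio",
    "Sphericity", "SphericalDisproportion", "Maximum2DDiameterSlice",
    "MajorAxisLength", "MinorAxisLength", "Elongation", "Perimeter",
    "PerimeterSurfaceRatio",
)


def _contour_geometry(mask: np.ndarray,
                      spacing: tuple[float, float]) -> tuple[float, float]:
    """(perimeter mm, enclosed area mm^2) of the marching-squares contour."""
    perim = 0.0
    area = 0.0
    padded = np.pad(mask.astype(np.float64), 1)  # guarantee closed contours
    for contour in find_contours(padded, 0.5):
        phys = contour * np.array(spacing)  # (row, col) -> mm
        d = np.diff(phys, axis=0)
        perim += float(np.sqrt((d ** 2).sum(axis=1)).sum())
        y, x = phys[:, 0], phys[:, 1]
        # shoelace; find_contours closes the loop for interior regions
        area += 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    return perim, abs(area)


def _max_diameter(mask: np.ndarray, spacing: tuple[float, float]) -> float:
    """Maximum pairwise distance between boundary pixel centres, in mm."""
    m = mask
    interior = np.zeros_like(m)
    interior[1:-1, 1:-1] = (m[1:-1, 1:-1] & m[:-2, 1:-1] & m[2:, 1:-1]
                            & m[1:-1, :-2] & m[1:-1, 2:])
    boundary = m & ~interior
    coords = np.argwhere(boundary).astype(np.float64) * np.array(spacing)
    if coords.shape[0] == 1:
        return 0.0
    if coords.shape[0] > 3:
        try:
            coords = coords[ConvexHull(coords).vertices]
        except Exception:  # degenerate (collinear) point sets
            pass
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.max()))


def shape_features(mask: BinaryMask, slice_thickness: float = 1.0
                   ) -> dict[str, float]:
    m = mask.values
    if not m.any():
        raise ValueError("empty mask")
    if label(m, connectivity=2).max() != 1:
        raise ValueError("shape features need a single connected component")
    sp = mask.spacing
    t = slice_thickness

    perimeter, mesh_area = _contour_geometry(m, sp)
    n_px = int(m.sum())
    voxel_volume = n_px * sp[0] * sp[1] * t
    mesh_volume = mesh_area * t
    surface_area = 2.0 * mesh_area + perimeter * t

    # principal axes from the covariance of physical pixel-centre coordinates
    coords = np.argwhere(m).astype(np.float64) * np.array(sp)
    cov = np.cov(coords, rowvar=False, bias=False)
    eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
    eig = np.clip(eig, 0.0, None)
    major = 4.0 * np.sqrt(eig[0])
    minor = 4.0 * np.sqrt(eig[1])
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0

    sphericity = ((36.0 * np.pi * mesh_volume ** 2) ** (1.0 / 3.0)
                  / surface_area)
    return {
        "MeshVolume": mesh_volume,
        "VoxelVolume": voxel_volume,
        "SurfaceArea": surface_area,
        "SurfaceVolumeRatio": surface_area / mesh_volume,
        "Sphericity": float(sphericity),
        "SphericalDisproportion": float(1.0 / sphericity),
        "Maximum2DDiameterSlice": _max_diameter(m, sp),
        "MajorAxisLength": float(major),
        "MinorAxisLength": float(minor),
        "Elongation": elongation,
        "Perimeter": perimeter,
        "PerimeterSurfaceRatio": perimeter / surface_area,
    }
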