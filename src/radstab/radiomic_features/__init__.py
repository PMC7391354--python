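"""The full radiomic signature: 18 first-order, 12 shape, 22 GLCM, 16 GLSZM,
16 GLRLM and 5 NGTDM features (89 in total), extracted from a discretized
ROI under a fixed preprocessing protocol. Feature values are raw (no
scaling); column names are "<category>_<FeatureName>" in a stable order.
"""

from __future__ import annotations

import numpy as np

from ..grids import BinaryMask, ImageGrid
from ..preprocess import (DiscretizedROI, PreprocessConfig, discretize,
                          eligibility_filter)
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .matrices import (ANGLES_2D, TextureMatrix, build_glcm, build_glrlm,
                       build_glszm, build_ngtdm)
from .shape2d import SHAPE_NAMES, shape_features
from .texture_features import (GLCM_NAMES, GLRLM_NAMES, GLSZM_NAMES,
                               NGTDM_NAMES, glcm_features, glrlm_features,
                               glszm_features, ngtdm_features)

__all__ = [
    "FEATURE_NAMES", "CATEGORY_COUNTS", "extract_all", "extract_from_roi",
    "firstorder_features", "shape_features", "build_glcm", "glcm_features",
    "build_glrlm", "glrlm_features", "build_glszm", "glszm_features",
    "build_ngtdm", "ngtdm_features", "TextureMatrix", "ANGLES_2D",
]

CATEGORY_COUNTS = {"firstorder": 18, "shape": 12, "glcm": 22,
                   "glszm": 16, "glrlm": 16, "ngtdm": 5}

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    + [f"shape_{n}" for n in SHAPE_NAMES]
    + [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"glszm_{n}" for n in GLSZM_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_NAMES]
)
N_FEATURES = sum(CATEGORY_COUNTS.values())
assert len(FEATURE_NAMES) == N_FEATURES


def extract_from_roi(roi: DiscretizedROI, mask: BinaryMask,
                     slice_thickness: float = 1.0) -> dict[str, float]:
    """All features from an already-discretized ROI."""
    n_px = int(roi.mask.sum())
    out: dict[str, float] = {}
    for n, v in firstorder_features(roi, slice_thickness).items():
        out[f"firstorder_{n}"] = v
    for n, v in shape_features(mask, slice_thickness).items():
        out[f"shape_{n}"] = v
    for n, v in glcm_features(build_glcm(roi)).items():
        out[f"glcm_{n}"] = v
    for n, v in glszm_features(build_glszm(roi), n_px).items():
        out[f"glszm_{n}"] = v
    for n, v in glrlm_features(build_glrlm(roi), n_px).items():
        out[f"glrlm_{n}"] = v
    for n, v in ngtdm_features(build_ngtdm(roi)).items():
        out[f"ngtdm_{n}"] = v
    return {name: out[name] for name in FEATURE_NAMES}


def extract_all(image: ImageGrid, mask: BinaryMask,
                cfg: PreprocessConfig | None = None) -> dict[str, float]:
    """Discretize and extract the full feature vector for one ROI.

    The mask must pass the eligibility filter (single component, minimum
    volume); values are returned unscaled in the stable FEATURE_NAMES order.
    """
    cfg = cfg or PreprocessConfig()
    elig = eligibility_filter(mask, slice_thickness=cfg.slice_thickness_mm,
                              min_volume=cfg.min_volume_mm3)
    if not elig:
        raise ValueError(f"ineligible mask: {elig.reason}")
    roi = discretize(image, mask, bin_width=cfg.bin_width_hu)
    return extract_from_roi(roi, mask, slice_thickness=cfg.slice_thickness_mm)
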