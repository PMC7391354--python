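"""First-order (intensity statistics) features: 18 values.

Computed on the raw in-mask HU values, except Entropy and Uniformity which
use the discretized gray-level histogram (the same fixed-bin-width levels
that feed the texture matrices). Entropies are in bits (log base 2);
Variance is the population variance and Kurtosis is non-excess.
"""

from __future__ import annotations

import numpy as np

from ..preprocess import DiscretizedROI

__all__ = ["firstorder_features", "FIRSTORDER_NAMES"]

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "Skewness", "Kurtosis", "Variance", "Uniformity",
)


def firstorder_features(roi: DiscretizedROI,
                        slice_thickness: float = 1.0) -> dict[str, float]:
    x = roi.raw
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    voxel_volume = roi.spacing[0] * roi.spacing[1] * slice_thickness

    counts = np.bincount(roi.in_mask_levels)[1:]
    p = counts[counts > 0] / n

    mean = float(x.mean())
    var = float(np.mean((x - mean) ** 2))
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]

    if var > 0:
        m = x - mean
        skew = float(np.mean(m ** 3) / var ** 1.5)
        kurt = float(np.mean(m ** 4) / var ** 2)
    else:
        skew, kurt = 0.0, 0.0

    energy = float(np.sum(x ** 2))
    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(p50),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.mean(np.abs(x - mean))),
        "RobustMeanAbsoluteDeviation":
            float(np.mean(np.abs(robust - robust.mean()))),
        "RootMeanSquared": float(np.sqrt(np.mean(x ** 2))),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float(np.sum(p ** 2)),
    }
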