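"""Dice overlap and pairwise inter-rater agreement summaries.

The Dice coefficient 2|A∩B|/(|A|+|B|) is the sole overlap measure used;
pairwise matrices over a rater set (or across two sets) summarise how much
independent segmentations of the same lesion agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import BinaryMask

__all__ = ["dice", "pairwise_dice", "DiceMatrix"]


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice overlap of two masks; NaN (undefined) when both are empty."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    sa = int(a.values.sum())
    sb = int(b.values.sum())
    if sa + sb == 0:
        return float("nan")
    inter = int(np.logical_and(a.values, b.values).sum())
    return 2.0 * inter / (sa + sb)


@dataclass(frozen=True)
class DiceMatrix:
    """Pairwise Dice table with rater labels; symmetric with unit diagonal
    in within-set mode, rectangular in cross-set mode."""

    values: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    cross: bool
    n_undefined: int = 0

    def off_diagonal(self) -> np.ndarray:
        """Entries entering the summary: all (cross) or upper off-diagonal
        (within); undefined (NaN) pairs are dropped."""
        if self.cross:
            vals = self.values.ravel()
        else:
            iu = np.triu_indices(self.values.shape[0], k=1)
            vals = self.values[iu]
        return vals[~np.isnan(vals)]

    def summary(self) -> dict[str, float]:
        """Median and interquartile range of the pairwise Dice scores."""
        vals = self.off_diagonal()
        if vals.size == 0:
            return {"median": float("nan"), "iqr_low": float("nan"),
                    "iqr_high": float("nan"), "n_pairs": 0}
        return {
            "median": float(np.median(vals)),
            "iqr_low": float(np.percentile(vals, 25)),
            "iqr_high": float(np.percentile(vals, 75)),
            "n_pairs": int(vals.size),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def pairwise_dice(set_a: list[BinaryMask],
                  set_b: list[BinaryMask] | None = None,
                  labels_a: list[str] | None = None,
                  labels_b: list[str] | None = None) -> DiceMatrix:
    """Pairwise Dice matrix within one rater set or across two sets.

    Within-set mode (set_b is None) needs k >= 2 raters and returns the
    symmetric k x k matrix with unit diagonal; cross mode returns all
    |A| x |B| comparisons. Both-empty pairs are recorded as NaN and counted.
    """
    if set_b is None:
        k = len(set_a)
        if k < 2:
            raise ValueError("within-set comparison needs at least 2 raters")
        vals = np.ones((k, k))
        undef = 0
        for i in range(k):
            vals[i, i] = 1.0 if not set_a[i].is_empty() else float("nan")
            undef += int(np.isnan(vals[i, i]))
            for j in range(i + 1, k):
                d = dice(set_a[i], set_a[j])
                vals[i, j] = vals[j, i] = d
                undef += int(np.isnan(d))
        labels = tuple(labels_a or [f"rater_{i}" for i in range(k)])
        return DiceMatrix(vals, labels, labels, cross=False, n_undefined=undef)

    if not set_a or not set_b:
        raise ValueError("cross comparison needs two non-empty sets")
    vals = np.empty((len(set_a), len(set_b)))
    undef = 0
    for i, ma in enumerate(set_a):
        for j, mb in enumerate(set_b):
            vals[i, j] = dice(ma, mb)
            undef += int(np.isnan(vals[i, j]))
    la = tuple(labels_a or [f"a_{i}" for i in range(len(set_a))])
    lb = tuple(labels_b or [f"b_{j}" for j in range(len(set_b))])
    return DiceMatrix(vals, la, lb, cross=True, n_undefined=undef)
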