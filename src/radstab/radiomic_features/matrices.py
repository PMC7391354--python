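"""Gray-level texture matrix builders: GLCM, GLRLM, GLSZM, NGTDM.

All builders operate on a DiscretizedROI (levels 1..Ng inside the mask,
0 outside). Out-of-mask pixels never contribute: they break runs, bound
zones and are excluded from co-occurrence pairs and neighbourhoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from ..preprocess import DiscretizedROI

__all__ = ["TextureMatrix", "build_glcm", "build_glrlm", "build_glszm",
           "build_ngtdm", "ANGLES_2D"]

# The four unique 2D directions at a given pixel distance: 0, 45, 90, 135
# degrees as (row, col) offsets (opposite offsets are covered by symmetry).
ANGLES_2D: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass(frozen=True)
class TextureMatrix:
    """One texture table.

    kind  : GLCM | GLRLM | GLSZM | NGTDM
    table : GLCM: Ng x Ng probabilities (sums to 1, symmetric);
            GLRLM: Ng x max_run_length counts; GLSZM: Ng x max_zone_size
            counts; NGTDM: Ng x 3 columns (n_i, p_i, s_i).
    ng    : number of gray levels (rows).
    offset: (row, col) direction for directional matrices, else None.
    """

    kind: str
    table: np.ndarray
    ng: int
    offset: tuple[int, int] | None = None


def build_glcm(roi: DiscretizedROI, distance: int = 1,
               angles: tuple[tuple[int, int], ...] = ANGLES_2D
               ) -> list[TextureMatrix]:
    """Symmetric, normalised co-occurrence matrix for each direction.

    A pair is counted when both endpoints of the offset lie inside the mask;
    each pair contributes to (i, j) and (j, i).
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    ng = roi.ng
    if ng == 0:
        raise ValueError("ROI has no gray levels")
    lv = roi.levels
    h, w = lv.shape
    out = []
    for dr, dc in angles:
        dr_, dc_ = dr * distance, dc * distance
        r0, r1 = max(0, -dr_), min(h, h - dr_)
        c0, c1 = max(0, -dc_), min(w, w - dc_)
        a = lv[r0:r1, c0:c1]
        b = lv[r0 + dr_:r1 + dr_, c0 + dc_:c1 + dc_]
        valid = (a > 0) & (b > 0)
        counts = np.zeros((ng, ng), dtype=np.float64)
        np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
        counts = counts + counts.T  # symmetric: count both pair orders
        total = counts.sum()
        table = counts / total if total > 0 else counts
        out.append(TextureMatrix("GLCM", table, ng, (dr, dc)))
    return out


def _line_runs(line: np.ndarray, counts: np.ndarray) -> None:
    """Accumulate maximal same-level runs of one 1D line into counts[i, l-1];
    zeros (out-of-mask) terminate runs and are not counted."""
    cur = 0
    run = 0
    for v in line:
        if v == cur:
            run += 1
        else:
            if cur > 0:
                counts[cur - 1, run - 1] += 1
            cur = int(v)
            run = 1
    if cur > 0:
        counts[cur - 1, run - 1] += 1


def build_glrlm(roi: DiscretizedROI,
                angles: tuple[tuple[int, int], ...] = ANGLES_2D
                ) -> list[TextureMatrix]:
    """Run-length matrix (counts) for each of the four 2D directions."""
    ng = roi.ng
    if ng == 0:
        raise ValueError("ROI has no gray levels")
    lv = roi.levels
    h, w = lv.shape
    max_len = max(h, w)
    out = []
    for dr, dc in angles:
        counts = np.zeros((ng, max_len), dtype=np.float64)
        if (dr, dc) == (0, 1):
            lines = [lv[r, :] for r in range(h)]
        elif (dr, dc) == (-1, 0):
            lines = [lv[:, c] for c in range(w)]
        elif (dr, dc) == (-1, 1):
            # anti-diagonals: constant r + c
            flipped = lv[::-1, :]
            lines = [np.diagonal(flipped, offset=o)
                     for o in range(-(h - 1), w)]
        elif (dr, dc) == (-1, -1):
            lines = [np.diagonal(lv, offset=o) for o in range(-(h - 1), w)]
        else:
            raise ValueError(f"unsupported direction {(dr, dc)}")
        for line in lines:
            _line_runs(np.asarray(line), counts)
        last = np.flatnonzero(counts.any(axis=0))
        trim = (last[-1] + 1) if last.size else 1
        out.append(TextureMatrix("GLRLM", counts[:, :trim], ng, (dr, dc)))
    return out


def build_glszm(roi: DiscretizedROI) -> TextureMatrix:
    """Size-zone matrix: 8-connected same-level in-mask components,
    counted by level and zone size. Single matrix, no directions."""
    ng = roi.ng
    if ng == 0:
        raise ValueError("ROI has no gray levels")
    lv = roi.levels
    n_px = int(roi.mask.sum())
    counts = np.zeros((ng, n_px), dtype=np.float64)
    for level in np.unique(lv[roi.mask]):
        lab = label(lv == level, connectivity=2)
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            counts[level - 1, s - 1] += 1
    last = np.flatnonzero(counts.any(axis=0))
    trim = (last[-1] + 1) if last.size else 1
    return TextureMatrix("GLSZM", counts[:, :trim], ng)


def build_ngtdm(roi: DiscretizedROI) -> TextureMatrix:
    """Neighbourhood gray-tone difference table.

    For each level i: n_i = number of in-mask pixels at level i that have at
    least one in-mask 8-neighbour, p_i = n_i / Nvp, and
    s_i = sum over those pixels of |i - mean(in-mask 8-neighbour levels)|.
    Columns of the table: (n_i, p_i, s_i).
    """
    ng = roi.ng
    if ng == 0:
        raise ValueError("ROI has no gray levels")
    lv = roi.levels.astype(np.float64)
    m = roi.mask
    pad_lv = np.pad(lv * m, 1)
    pad_m = np.pad(m.astype(np.float64), 1)
    # 8-neighbour sums via explicit shifts (small kernel, exact arithmetic)
    nb_sum = np.zeros_like(lv)
    nb_cnt = np.zeros_like(lv)
    h, w = lv.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            nb_sum += pad_lv[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
            nb_cnt += pad_m[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]
    valid = m & (nb_cnt > 0)
    nvp = int(valid.sum())
    table = np.zeros((ng, 3), dtype=np.float64)
    if nvp == 0:
        return TextureMatrix("NGTDM", table, ng)
    diffs = np.abs(lv - nb_sum / np.where(nb_cnt > 0, nb_cnt, 1.0))
    for i in range(1, ng + 1):
        sel = valid & (roi.levels == i)
        n_i = int(sel.sum())
        table[i - 1, 0] = n_i
        table[i - 1, 1] = n_i / nvp
        table[i - 1, 2] = diffs[sel].sum()
    return TextureMatrix("NGTDM", table, ng)
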