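"""Independent brute-force oracles for texture matrices, texture features
and ICC, written as plain loops so they share no code path with the package
implementation they check."""

from __future__ import annotations

import math

import numpy as np


# --------------------------------------------------------------------------
# texture matrix oracles (levels: 2D int array, 0 = outside mask)

def naive_glcm(levels: np.ndarray, ng: int, offset: tuple[int, int],
               distance: int = 1) -> np.ndarray:
    """Symmetric normalised co-occurrence matrix by pair enumeration."""
    h, w = levels.shape
    dr, dc = offset[0] * distance, offset[1] * distance
    counts = np.zeros((ng, ng))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = levels[r, c], levels[r2, c2]
                if a > 0 and b > 0:
                    counts[a - 1, b - 1] += 1
                    counts[b - 1, a - 1] += 1
    tot = counts.sum()
    return counts / tot if tot > 0 else counts


def naive_glrlm(levels: np.ndarray, ng: int,
                offset: tuple[int, int]) -> np.ndarray:
    """Run-length counts by walking every line in the offset direction."""
    h, w = levels.shape
    dr, dc = offset
    counts = np.zeros((ng, max(h, w)))
    starts = [(r, c) for r in range(h) for c in range(w)
              if not (0 <= r - dr < h and 0 <= c - dc < w)]
    for r0, c0 in starts:
        r, c = r0, c0
        cur, run = 0, 0
        while 0 <= r < h and 0 <= c < w:
            v = levels[r, c]
            if v == cur:
                run += 1
            else:
                if cur > 0:
                    counts[cur - 1, run - 1] += 1
                cur, run = v, 1
            r, c = r + dr, c + dc
        if cur > 0:
            counts[cur - 1, run - 1] += 1
    return counts


def naive_glszm(levels: np.ndarray, ng: int) -> np.ndarray:
    """Zone counts by explicit 8-connected flood fill per level."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    counts = np.zeros((ng, h * w))
    for r in range(h):
        for c in range(w):
            if levels[r, c] > 0 and not seen[r, c]:
                lvl = levels[r, c]
                stack = [(r, c)]
                seen[r, c] = True
                size = 0
                while stack:
                    rr, cc = stack.pop()
                    size += 1
                    for dr in (-1, 0, 1):
                        for dc in (-1, 0, 1):
                            r2, c2 = rr + dr, cc + dc
                            if (0 <= r2 < h and 0 <= c2 < w
                                    and not seen[r2, c2]
                                    and levels[r2, c2] == lvl):
                                seen[r2, c2] = True
                                stack.append((r2, c2))
                counts[lvl - 1, size - 1] += 1
    return counts


def naive_ngtdm(levels: np.ndarray, ng: int) -> np.ndarray:
    """(n_i, p_i, s_i) table by per-pixel neighbour scan."""
    h, w = levels.shape
    per_pixel = []  # (level, |level - neighbour mean|)
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0:
                continue
            nb = []
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    r2, c2 = r + dr, c + dc
                    if 0 <= r2 < h and 0 <= c2 < w and levels[r2, c2] > 0:
                        nb.append(levels[r2, c2])
            if nb:
                per_pixel.append((levels[r, c],
                                  abs(levels[r, c] - sum(nb) / len(nb))))
    nvp = len(per_pixel)
    table = np.zeros((ng, 3))
    for i in range(1, ng + 1):
        diffs = [d for (lv, d) in per_pixel if lv == i]
        table[i - 1, 0] = len(diffs)
        table[i - 1, 1] = len(diffs) / nvp if nvp else 0.0
        table[i - 1, 2] = sum(diffs)
    return table


# --------------------------------------------------------------------------
# texture feature oracles: scalar loops over matrix entries

def _entropy2(ps) -> float:
    return -sum(p * math.log2(p) for p in ps if p > 0)


def naive_glcm_features(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    lv = list(range(1, ng + 1))
    px = [sum(p[i - 1, j - 1] for j in lv) for i in lv]
    py = [sum(p[i - 1, j - 1] for i in lv) for j in lv]
    mu_x = sum(i * px[i - 1] for i in lv)
    mu_y = sum(j * py[j - 1] for j in lv)
    sig_x = math.sqrt(sum(px[i - 1] * (i - mu_x) ** 2 for i in lv))
    sig_y = math.sqrt(sum(py[j - 1] * (j - mu_y) ** 2 for j in lv))
    p_diff = [sum(p[i - 1, j - 1] for i in lv for j in lv
                  if abs(i - j) == k) for k in range(ng)]
    p_sum = [sum(p[i - 1, j - 1] for i in lv for j in lv
                 if i + j == k) for k in range(2, 2 * ng + 1)]
    hx, hy = _entropy2(px), _entropy2(py)
    hxy = _entropy2(p.ravel())
    hxy1 = -sum(p[i - 1, j - 1] * math.log2(px[i - 1] * py[j - 1])
                for i in lv for j in lv
                if p[i - 1, j - 1] > 0 and px[i - 1] * py[j - 1] > 0)
    hxy2 = _entropy2([px[i - 1] * py[j - 1] for i in lv for j in lv])
    da = sum(k * p_diff[k] for k in range(ng))
    out = {
        "Autocorrelation": sum(i * j * p[i - 1, j - 1] for i in lv for j in lv),
        "ClusterProminence": sum((i + j - mu_x - mu_y) ** 4 * p[i - 1, j - 1]
                                 for i in lv for j in lv),
        "ClusterShade": sum((i + j - mu_x - mu_y) ** 3 * p[i - 1, j - 1]
                            for i in lv for j in lv),
        "ClusterTendency": sum((i + j - mu_x - mu_y) ** 2 * p[i - 1, j - 1]
                               for i in lv for j in lv),
        "Contrast": sum((i - j) ** 2 * p[i - 1, j - 1] for i in lv for j in lv),
        "Correlation": ((sum(i * j * p[i - 1, j - 1] for i in lv for j in lv)
                         - mu_x * mu_y) / (sig_x * sig_y)
                        if sig_x > 0 and sig_y > 0 else 1.0),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": sum((k - da) ** 2 * p_diff[k] for k in range(ng)),
        "JointAverage": mu_x,
        "JointEnergy": sum(p[i - 1, j - 1] ** 2 for i in lv for j in lv),
        "JointEntropy": hxy,
        "Imc1": (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0,
        "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
        "Idm": sum(p[i - 1, j - 1] / (1 + (i - j) ** 2) for i in lv for j in lv),
        "Idmn": sum(p[i - 1, j - 1] / (1 + (i - j) ** 2 / ng ** 2)
                    for i in lv for j in lv),
        "Id": sum(p[i - 1, j - 1] / (1 + abs(i - j)) for i in lv for j in lv),
        "Idn": sum(p[i - 1, j - 1] / (1 + abs(i - j) / ng)
                   for i in lv for j in lv),
        "InverseVariance": sum(p[i - 1, j - 1] / (i - j) ** 2
                               for i in lv for j in lv if i != j),
        "MaximumProbability": max(p[i - 1, j - 1] for i in lv for j in lv),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": sum((i - mu_x) ** 2 * p[i - 1, j - 1]
                          for i in lv for j in lv),
    }
    return out


def naive_rlm_features(counts: np.ndarray, n_px: int) -> dict[str, float]:
    """Run-length/size-zone feature formulas by scalar loops; generic keys."""
    ng, nl = counts.shape
    nr = counts.sum()
    lv = list(range(1, ng + 1))
    ln = list(range(1, nl + 1))
    gi = [sum(counts[i - 1, l - 1] for l in ln) for i in lv]
    rl = [sum(counts[i - 1, l - 1] for i in lv) for l in ln]
    p = counts / nr
    mu_i = sum(i * p[i - 1, l - 1] for i in lv for l in ln)
    mu_l = sum(l * p[i - 1, l - 1] for i in lv for l in ln)
    return {
        "small": sum(counts[i - 1, l - 1] / l ** 2 for i in lv for l in ln) / nr,
        "large": sum(counts[i - 1, l - 1] * l ** 2 for i in lv for l in ln) / nr,
        "gln": sum(g ** 2 for g in gi) / nr,
        "glnn": sum(g ** 2 for g in gi) / nr ** 2,
        "rln": sum(r ** 2 for r in rl) / nr,
        "rlnn": sum(r ** 2 for r in rl) / nr ** 2,
        "pct": nr / n_px,
        "glv": sum(p[i - 1, l - 1] * (i - mu_i) ** 2 for i in lv for l in ln),
        "rv": sum(p[i - 1, l - 1] * (l - mu_l) ** 2 for i in lv for l in ln),
        "ent": _entropy2(p.ravel()),
        "lgl": sum(counts[i - 1, l - 1] / i ** 2 for i in lv for l in ln) / nr,
        "hgl": sum(counts[i - 1, l - 1] * i ** 2 for i in lv for l in ln) / nr,
        "slgl": sum(counts[i - 1, l - 1] / (i ** 2 * l ** 2)
                    for i in lv for l in ln) / nr,
        "shgl": sum(counts[i - 1, l - 1] * i ** 2 / l ** 2
                    for i in lv for l in ln) / nr,
        "llgl": sum(counts[i - 1, l - 1] * l ** 2 / i ** 2
                    for i in lv for l in ln) / nr,
        "lhgl": sum(counts[i - 1, l - 1] * i ** 2 * l ** 2
                    for i in lv for l in ln) / nr,
    }


RLM_KEYMAP = {
    "run": {
        "small": "ShortRunEmphasis", "large": "LongRunEmphasis",
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "rln": "RunLengthNonUniformity",
        "rlnn": "RunLengthNonUniformityNormalized",
        "pct": "RunPercentage", "glv": "GrayLevelVariance",
        "rv": "RunVariance", "ent": "RunEntropy",
        "lgl": "LowGrayLevelRunEmphasis", "hgl": "HighGrayLevelRunEmphasis",
        "slgl": "ShortRunLowGrayLevelEmphasis",
        "shgl": "ShortRunHighGrayLevelEmphasis",
        "llgl": "LongRunLowGrayLevelEmphasis",
        "lhgl": "LongRunHighGrayLevelEmphasis",
    },
    "zone": {
        "small": "SmallAreaEmphasis", "large": "LargeAreaEmphasis",
        "gln": "GrayLevelNonUniformity",
        "glnn": "GrayLevelNonUniformityNormalized",
        "rln": "SizeZoneNonUniformity",
        "rlnn": "SizeZoneNonUniformityNormalized",
        "pct": "ZonePercentage", "glv": "GrayLevelVariance",
        "rv": "ZoneVariance", "ent": "ZoneEntropy",
        "lgl": "LowGrayLevelZoneEmphasis", "hgl": "HighGrayLevelZoneEmphasis",
        "slgl": "SmallAreaLowGrayLevelEmphasis",
        "shgl": "SmallAreaHighGrayLevelEmphasis",
        "llgl": "LargeAreaLowGrayLevelEmphasis",
        "lhgl": "LargeAreaHighGrayLevelEmphasis",
    },
}


def naive_ngtdm_features(table: np.ndarray) -> dict[str, float]:
    ng = table.shape[0]
    n_i = table[:, 0]
    p_i = table[:, 1]
    s_i = table[:, 2]
    nvp = n_i.sum()
    present = [i for i in range(1, ng + 1) if p_i[i - 1] > 0]
    ngp = len(present)
    denom = sum(p_i[i - 1] * s_i[i - 1] for i in present)
    coarseness = min(1.0 / denom if denom > 0 else 1e6, 1e6)
    if ngp > 1:
        contrast = (sum(p_i[i - 1] * p_i[j - 1] * (i - j) ** 2
                        for i in present for j in present)
                    / (ngp * (ngp - 1)) * sum(s_i) / nvp)
    else:
        contrast = 0.0
    busy_den = sum(abs(i * p_i[i - 1] - j * p_i[j - 1])
                   for i in present for j in present)
    busyness = denom / busy_den if busy_den > 0 else 0.0
    complexity = sum(abs(i - j) * (p_i[i - 1] * s_i[i - 1]
                                   + p_i[j - 1] * s_i[j - 1])
                     / (p_i[i - 1] + p_i[j - 1])
                     for i in present for j in present) / nvp
    s_tot = sum(s_i)
    strength = (sum((p_i[i - 1] + p_i[j - 1]) * (i - j) ** 2
                    for i in present for j in present) / s_tot
                if s_tot > 0 else 0.0)
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


# --------------------------------------------------------------------------
# ICC oracle: explicit one-way ANOVA sums of squares

def naive_icc_1_1(table: np.ndarray) -> float:
    n, k = table.shape
    grand = table.sum() / (n * k)
    row_means = [sum(table[i]) / k for i in range(n)]
    ssb = k * sum((rm - grand) ** 2 for rm in row_means)
    ssw = sum((table[i, j] - row_means[i]) ** 2
              for i in range(n) for j in range(k))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    if msw == 0:
        return 1.0 if msb > 0 else float("nan")
    return (msb - msw) / (msb + (k - 1) * msw)
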