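"""Feature formulas over the four texture matrices.

Directional matrices (GLCM, GLRLM) are reduced by computing every feature
per direction and averaging over the four 2D directions. Entropies use log
base 2 with the 0·log 0 := 0 convention. Degenerate single-level ROIs take
the documented limit values (Correlation 1, Imc1/Imc2 0, InverseVariance 0,
NGTDM Coarseness capped at 1e6).
"""

from __future__ import annotations

import numpy as np

from .matrices import TextureMatrix

__all__ = [
    "glcm_features", "glrlm_features", "glszm_features", "ngtdm_features",
    "GLCM_NAMES", "GLRLM_NAMES", "GLSZM_NAMES", "NGTDM_NAMES",
]

_EPS = np.spacing(1.0)
COARSENESS_CAP = 1e6

GLCM_NAMES = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "JointAverage", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy", "SumSquares",
)

GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis",
)

GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
)

NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")


def _xlog2x(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)          # marginal over rows (== cols by symmetry)
    py = p.sum(axis=0)
    mu_x = float(np.sum(i * px))
    mu_y = float(np.sum(i * py))
    sig_x = float(np.sqrt(np.sum(px * (i - mu_x) ** 2)))
    sig_y = float(np.sqrt(np.sum(py * (i - mu_y) ** 2)))

    # diagonal (difference) and cross-diagonal (sum) distributions
    k_diff = np.arange(0, ng, dtype=np.float64)
    p_diff = np.zeros(ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    absdiff = np.abs(ii - jj).astype(np.int64)
    sums = (ii + jj).astype(np.int64)
    np.add.at(p_diff, absdiff.ravel(), p.ravel())
    np.add.at(p_sum, sums.ravel() - 2, p.ravel())

    hx = float(-np.sum(_xlog2x(px)))
    hy = float(-np.sum(_xlog2x(py)))
    hxy = float(-np.sum(_xlog2x(p)))
    outer = np.outer(px, py)
    nz = (p > 0) & (outer > 0)
    hxy1 = float(-np.sum(p[nz] * np.log2(outer[nz])))
    nz2 = outer > 0
    hxy2 = float(-np.sum(outer[nz2] * np.log2(outer[nz2])))

    diff_avg = float(np.sum(k_diff * p_diff))
    contrast = float(np.sum((ii - jj) ** 2 * p))

    if sig_x > 0 and sig_y > 0:
        corr = float((np.sum(ii * jj * p) - mu_x * mu_y) / (sig_x * sig_y))
    else:
        corr = 1.0  # single-level limit
    if max(hx, hy) > 0:
        imc1 = float((hxy - hxy1) / max(hx, hy))
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    off = ii != jj
    inv_var = float(np.sum(p[off] / (ii - jj)[off] ** 2)) if off.any() else 0.0

    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "ClusterProminence": float(np.sum((ii + jj - mu_x - mu_y) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - mu_x - mu_y) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - mu_x - mu_y) ** 2 * p)),
        "Contrast": contrast,
        "Correlation": corr,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(_xlog2x(p_diff))),
        "DifferenceVariance": float(np.sum((k_diff - diff_avg) ** 2 * p_diff)),
        "JointAverage": mu_x,
        "JointEnergy": float(np.sum(p ** 2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + (ii - jj) ** 2 / ng ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(_xlog2x(p_sum))),
        "SumSquares": float(np.sum((ii - mu_x) ** 2 * p)),
    }


def glcm_features(matrices: list[TextureMatrix]) -> dict[str, float]:
    """22 co-occurrence features, averaged over directions."""
    if not matrices:
        raise ValueError("need at least one GLCM")
    per_angle = [_glcm_single(m.table) for m in matrices]
    return {name: float(np.mean([f[name] for f in per_angle]))
            for name in GLCM_NAMES}


def _rlm_single(counts: np.ndarray, n_px: int,
                size_word: str) -> dict[str, float]:
    """Shared run-length / size-zone feature arithmetic.

    counts[i, l-1] = number of runs (zones) of gray level i+1 and length
    (size) l; n_px = in-mask pixel count. size_word selects the GLRLM or
    GLSZM naming scheme.
    """
    nr = counts.sum()
    if nr == 0:
        raise ValueError("empty run/zone matrix")
    ng, nl = counts.shape
    i = np.arange(1, ng + 1, dtype=np.float64)
    l = np.arange(1, nl + 1, dtype=np.float64)
    gi = counts.sum(axis=1)     # per-level totals
    rl = counts.sum(axis=0)     # per-length totals
    p = counts / nr
    mu_i = float(np.sum(p.sum(axis=1) * i))
    mu_l = float(np.sum(p.sum(axis=0) * l))
    ii = i[:, None]
    ll = l[None, :]

    run = {"run": "Run", "zone": "Zone"}[size_word]
    small = {"run": "ShortRun", "zone": "SmallArea"}[size_word]
    large = {"run": "LongRun", "zone": "LargeArea"}[size_word]
    rln = {"run": "RunLengthNonUniformity",
           "zone": "SizeZoneNonUniformity"}[size_word]
    lvl_emph = {"run": "GrayLevelRunEmphasis",
                "zone": "GrayLevelZoneEmphasis"}[size_word]
    # combined small/large x low/high names drop the run/zone word
    comb = "GrayLevelEmphasis"

    return {
        f"{small}Emphasis": float(np.sum(counts / ll ** 2) / nr),
        f"{large}Emphasis": float(np.sum(counts * ll ** 2) / nr),
        "GrayLevelNonUniformity": float(np.sum(gi ** 2) / nr),
        "GrayLevelNonUniformityNormalized": float(np.sum(gi ** 2) / nr ** 2),
        rln: float(np.sum(rl ** 2) / nr),
        f"{rln}Normalized": float(np.sum(rl ** 2) / nr ** 2),
        f"{run}Percentage": float(nr / n_px),
        "GrayLevelVariance": float(np.sum(p * (ii - mu_i) ** 2)),
        f"{run}Variance": float(np.sum(p * (ll - mu_l) ** 2)),
        f"{run}Entropy": float(-np.sum(_xlog2x(p))),
        f"Low{lvl_emph}": float(np.sum(counts / ii ** 2) / nr),
        f"High{lvl_emph}": float(np.sum(counts * ii ** 2) / nr),
        f"{small}Low{comb}": float(np.sum(counts / (ii ** 2 * ll ** 2)) / nr),
        f"{small}High{comb}": float(np.sum(counts * ii ** 2 / ll ** 2) / nr),
        f"{large}Low{comb}": float(np.sum(counts * ll ** 2 / ii ** 2) / nr),
        f"{large}High{comb}": float(np.sum(counts * ii ** 2 * ll ** 2) / nr),
    }


def glrlm_features(matrices: list[TextureMatrix],
                   n_px: int) -> dict[str, float]:
    """16 run-length features, averaged over the four directions."""
    if not matrices:
        raise ValueError("need at least one GLRLM")
    per_angle = [_rlm_single(m.table, n_px, "run") for m in matrices]
    return {name: float(np.mean([f[name] for f in per_angle]))
            for name in GLRLM_NAMES}


def glszm_features(matrix: TextureMatrix, n_px: int) -> dict[str, float]:
    """16 size-zone features from the single (direction-free) matrix."""
    return {name: v for name, v in _rlm_single(matrix.table, n_px,
                                               "zone").items()}


def ngtdm_features(matrix: TextureMatrix) -> dict[str, float]:
    """5 neighbourhood gray-tone difference features."""
    tab = matrix.table
    n_i, p_i, s_i = tab[:, 0], tab[:, 1], tab[:, 2]
    present = p_i > 0
    nvp = n_i.sum()
    if nvp == 0:
        raise ValueError("NGTDM has no valid pixels")
    ngp = int(present.sum())
    i = np.arange(1, tab.shape[0] + 1, dtype=np.float64)

    denom_coarse = float(np.sum(p_i * s_i))
    coarseness = (1.0 / denom_coarse if denom_coarse > 0 else COARSENESS_CAP)
    coarseness = min(coarseness, COARSENESS_CAP)

    ip, pp, sp_ = i[present], p_i[present], s_i[present]
    if ngp > 1:
        dif2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = (float(np.sum(pp[:, None] * pp[None, :] * dif2))
                    / (ngp * (ngp - 1)) * float(s_i.sum()) / nvp)
    else:
        contrast = 0.0

    busy_denom = float(np.sum(np.abs(ip[:, None] * pp[:, None]
                                     - ip[None, :] * pp[None, :])))
    busyness = denom_coarse / busy_denom if busy_denom > 0 else 0.0

    pisi = pp * sp_
    with np.errstate(invalid="ignore"):
        cplx = (np.abs(ip[:, None] - ip[None, :])
                * (pisi[:, None] + pisi[None, :])
                / (pp[:, None] + pp[None, :]))
    complexity = float(np.sum(cplx)) / nvp

    s_sum = float(s_i.sum())
    if s_sum > 0:
        strength = float(np.sum((pp[:, None] + pp[None, :])
                                * (ip[:, None] - ip[None, :]) ** 2)) / s_sum
    else:
        strength = 0.0

    return {
        "Coarseness": float(coarseness),
        "Contrast": float(contrast),
        "Busyness": float(busyness),
        "Complexity": float(complexity),
        "Strength": float(strength),
    }
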