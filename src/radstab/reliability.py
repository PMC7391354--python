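"""ICC(1,1) reliability of radiomic features across rater populations.

The intraclass correlation from a one-way random-effects model,

    ICC(1,1) = (MSB - MSW) / (MSB + (k - 1) MSW),

quantifies how much of a feature's variance is between lesions rather than
between the k raters segmenting each lesion: 1 means raters agree perfectly,
0 means rater disagreement swamps the biological signal. Confidence
intervals come from a lesion-level percentile bootstrap. Per-category
aggregation, population comparison and stability classification mirror the
downstream reporting of a reproducibility study.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ICCRecord", "icc_1_1", "bootstrap_ci", "icc_table", "category_summary",
    "compare_icc_vectors", "classify_stability",
]

# Feature columns are "<category>_<Name>"; categories in stable report order.
CATEGORIES = ("firstorder", "shape", "glcm", "glszm", "glrlm", "ngtdm")


@dataclass(frozen=True)
class ICCRecord:
    """Per-feature reliability result."""

    feature_name: str
    category: str
    icc: float              # NaN when undefined (zero total variance)
    ci_low: float
    ci_high: float
    n_lesions: int
    k_raters: int
    n_boot: int
    n_boot_undefined: int = 0

    @property
    def defined(self) -> bool:
        return not np.isnan(self.icc)


def _anova_mean_squares(table: np.ndarray) -> tuple[float, float]:
    """One-way random-effects mean squares (between-lesion, within-lesion)."""
    n, k = table.shape
    row_means = table.mean(axis=1)
    grand = table.mean()
    msb = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msw = np.sum((table - row_means[:, None]) ** 2) / (n * (k - 1))
    return float(msb), float(msw)


def icc_1_1(table: np.ndarray) -> float:
    """ICC(1,1) of an n_lesions x k_raters measurement table.

    Negative estimates are reported as-is (MSW exceeding MSB is informative,
    not an error). A table with zero total variance has no defined ICC and
    returns NaN; zero within-lesion variance with between-lesion signal
    returns exactly 1.
    """
    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need an n x k table with n >= 2 and k >= 2")
    if not np.all(np.isfinite(table)):
        raise ValueError("table contains non-finite values")
    msb, msw = _anova_mean_squares(table)
    k = table.shape[1]
    if msw == 0.0:
        return 1.0 if msb > 0 else float("nan")
    return (msb - msw) / (msb + (k - 1) * msw)


def _icc_batch(tables: np.ndarray) -> np.ndarray:
    """Vectorised ICC(1,1) over a stack of tables, shape (m, n, k)."""
    m, n, k = tables.shape
    row_means = tables.mean(axis=2)
    grand = tables.mean(axis=(1, 2))
    msb = k * np.sum((row_means - grand[:, None]) ** 2, axis=1) / (n - 1)
    msw = np.sum((tables - row_means[:, :, None]) ** 2, axis=(1, 2)) / (n * (k - 1))
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msb - msw) / (msb + (k - 1) * msw)
    icc[(msw == 0) & (msb > 0)] = 1.0
    icc[(msw == 0) & (msb == 0)] = np.nan
    return icc


def bootstrap_ci(table: np.ndarray, n_boot: int = 1000, alpha: float = 0.05,
                 seed: int = 0) -> tuple[float, float, int]:
    """Percentile bootstrap CI for ICC(1,1), resampling lesions (rows).

    Returns (low, high, n_undefined_replicates); undefined replicates are
    dropped from the percentile computation. More than 50% undefined
    replicates is an error.
    """
    table = np.asarray(table, dtype=np.float64)
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    n = table.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = _icc_batch(table[idx, :])
    undef = int(np.isnan(reps).sum())
    if undef > n_boot / 2:
        raise ValueError(
            f"{undef}/{n_boot} bootstrap replicates had undefined ICC")
    good = reps[~np.isnan(reps)]
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi), undef


def _category_of(feature_name: str) -> str:
    head = feature_name.split("_", 1)[0]
    return head if head in CATEGORIES else "unknown"


def icc_table(features: pd.DataFrame, n_boot: int = 1000, alpha: float = 0.05,
              seed: int = 0) -> pd.DataFrame:
    """Per-feature ICC(1,1) with bootstrap CIs over a feature table.

    `features` holds one row per (lesion, rater) with a 2-level index
    (lesion_id, rater_id) — the layout written by the extraction stage — and
    one column per feature. Lesions missing any rater are dropped whole.
    Constant-feature columns are reported with an undefined (NaN) ICC rather
    than silently dropped.
    """
    if not isinstance(features.index, pd.MultiIndex):
        raise ValueError("features must be indexed by (lesion_id, rater_id)")
    wide = features.unstack(level=-1)  # columns: (feature, rater)
    wide = wide.dropna(axis=0, how="any")
    n = wide.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete lesions")
    ss = np.random.SeedSequence(seed)
    records = []
    feat_names = list(features.columns)
    child_seeds = ss.generate_state(len(feat_names))
    for fname, fseed in zip(feat_names, child_seeds):
        tab = wide[fname].to_numpy(dtype=np.float64)
        k = tab.shape[1]
        est = icc_1_1(tab)
        if np.isnan(est):
            lo = hi = float("nan")
            undef = n_boot
        else:
            lo, hi, undef = bootstrap_ci(tab, n_boot=n_boot, alpha=alpha,
                                         seed=int(fseed))
        records.append(ICCRecord(fname, _category_of(fname), est, lo, hi,
                                 n, k, n_boot, undef))
    return pd.DataFrame([r.__dict__ for r in records])


def category_summary(records: pd.DataFrame,
                     thresholds: tuple[float, ...] = (0.75, 0.8, 0.9)
                     ) -> pd.DataFrame:
    """Mean ICC and fraction of features above each threshold, per category
    and overall. Fractions are over features with a defined ICC; the count
    of undefined features is reported alongside."""
    rows = []
    groups = [("all", records)] + [
        (cat, records[records["category"] == cat]) for cat in CATEGORIES
        if (records["category"] == cat).any()
    ]
    for name, grp in groups:
        defined = grp["icc"].dropna()
        row = {
            "category": name,
            "n_features": len(grp),
            "n_undefined": int(grp["icc"].isna().sum()),
            "mean_icc": float(defined.mean()) if len(defined) else float("nan"),
        }
        for t in thresholds:
            frac = float((defined > t).mean()) if len(defined) else float("nan")
            row[f"frac_icc_gt_{t}"] = frac
        rows.append(row)
    return pd.DataFrame(rows)


def compare_icc_vectors(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Pearson correlation of paired per-feature ICC estimates from two
    rater populations (e.g. expert readers vs sampled segmentations)."""
    merged = a.set_index("feature_name")[["icc"]].join(
        b.set_index("feature_name")[["icc"]], lsuffix="_a", rsuffix="_b",
        how="inner").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 common features with defined ICC")
    r, _ = stats.pearsonr(merged["icc_a"], merged["icc_b"])
    return float(r)


def classify_stability(icc: float) -> dict[str, str]:
    """Stability label under the two published conventions side by side:
    the 0.75 excellent-agreement rule and the stricter 0.90 rule."""
    if np.isnan(icc):
        return {"rule_075": "undefined", "rule_090": "undefined"}
    if icc < 0.4:
        c075 = "poor"
    elif icc < 0.6:
        c075 = "fair"
    elif icc <= 0.75:
        c075 = "good"
    else:
        c075 = "excellent"
    if icc < 0.5:
        c090 = "poor"
    elif icc < 0.75:
        c090 = "moderate"
    elif icc <= 0.9:
        c090 = "good"
    else:
        c090 = "excellent"
    return {"rule_075": c075, "rule_090": c090}
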