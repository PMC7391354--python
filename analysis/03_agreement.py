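"""Pairwise Dice agreement within and across the two rater populations.

For every lesion, computes the pairwise Dice matrix among the expert panel,
among the sampled raters, and between the two populations, then pools all
pairs and reports median and IQR — the overlap statistics that justify
treating the sampled raters as a stand-in for human readers.

Run:  python analysis/03_agreement.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from radstab.agreement import pairwise_dice
from radstab.synthetic_cohort import load_cohort

OUT = Path("results/analysis")
COHORT = Path("scratch/cohort")


def main() -> None:
    cases = load_cohort(COHORT)
    rows = []
    pooled: dict[str, list[np.ndarray]] = {
        "experts": [], "samples": [], "cross": []}
    for case in cases:
        mats = {
            "experts": pairwise_dice(list(case.expert_masks)),
            "samples": pairwise_dice(list(case.sample_masks)),
            "cross": pairwise_dice(list(case.sample_masks),
                                   list(case.expert_masks)),
        }
        for pop, mat in mats.items():
            pooled[pop].append(mat.off_diagonal())
            rows.append({"lesion_id": case.lesion_id, "population": pop,
                         **mat.summary()})
    per_lesion = pd.DataFrame(rows)
    per_lesion.to_csv(OUT / "dice_per_lesion.csv", index=False)

    print("pooled pairwise Dice (median [IQR]):")
    summary_rows = []
    for pop, chunks in pooled.items():
        vals = np.concatenate(chunks)
        med = np.median(vals)
        lo, hi = np.percentile(vals, [25, 75])
        summary_rows.append({"population": pop, "median": med,
                             "iqr_low": lo, "iqr_high": hi,
                             "n_pairs": vals.size})
        print(f"  {pop:8s}: {med:.3f} [{lo:.3f} {hi:.3f}]  "
              f"({vals.size} pairs)")
    pd.DataFrame(summary_rows).to_csv(OUT / "dice_pooled_summary.csv",
                                      index=False)


if __name__ == "__main__":
    main()
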