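"""Extract the full radiomic signature for every (lesion, rater) mask.

Reads the NIfTI cohort written by 01_simulate_cohort.py, applies the
extraction protocol (1 mm resampling, lesion-centred crop, 25 HU fixed-bin
discretization, 30 mm^3 eligibility floor) and writes one feature table per
rater population: results/analysis/features_{experts,samples}.csv with a
(lesion_id, rater_id) index and 89 feature columns.

Run:  python analysis/02_extract_features.py
"""

from __future__ import annotations

from pathlib import Path

from radstab.pipeline import extract_cohort_features
from radstab.preprocess import PreprocessConfig
from radstab.synthetic_cohort import load_cohort

OUT = Path("results/analysis")
COHORT = Path("scratch/cohort")


def main() -> None:
    cases = load_cohort(COHORT)
    cfg = PreprocessConfig(crop_size_px=64)
    for pop in ("experts", "samples"):
        table = extract_cohort_features(cases, cfg, pop)
        path = OUT / f"features_{pop}.csv"
        table.to_csv(path)
        print(f"{pop}: {table.shape[0]} feature vectors x "
              f"{table.shape[1]} features -> {path}")


if __name__ == "__main__":
    main()
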