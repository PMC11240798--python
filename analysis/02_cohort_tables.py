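#!/usr/bin/env python
"""Simulate the 57-patient synthetic cohort and build its cohort table.

Each patient is a seeded breathing-torso phantom (row-structured amplitude
field, BMI-damped rib-cage motion, upper-thorax phase lag, BMI-linked L4
adiposity).  The per-patient analysis (maps, nine-ROI summaries, SAT/VAT
percentages) runs on the analytic beam-length field at 37 slices x 5 mm, a
cohort-scale problem size chosen so the whole study runs in seconds.
Writes results/cohort.csv.
"""

import argparse
from pathlib import Path

from surrocor.cohort import build_cohort_table, synthesize_cohort


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-patients", type=int, default=57)
    parser.add_argument("--aggregator", choices=["mean", "median"], default="mean")
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    specs = synthesize_cohort(n_patients=args.n_patients, seed=args.seed)
    table = build_cohort_table(specs, aggregator=args.aggregator)
    table.to_csv(args.out / "cohort.csv", index=False)

    by_sex = table.groupby("sex")[
        ["mag_A", "mag_B", "mag_C", "r_A", "r_B", "r_C", "ts_magnitude_mm",
         "sat_pct", "vat_pct", "tat_pct"]
    ].median()
    print(f"cohort of {len(table)} patients written to {args.out / 'cohort.csv'}")
    print("\nmedians by sex:")
    print(by_sex.round(2).to_string())
    print("\nAs constructed: abdominal (B/C-row) magnitudes are larger for men,")
    print("rib-cage (A-row) magnitudes are comparable between sexes, and the")
    print("A-row correlation with the tracking structure is the weakest.")


if __name__ == "__main__":
    main()
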