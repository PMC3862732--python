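"""Univariate BM vs PB comparison at diagnosis (day 0) and remission (day 29).

For each metabolite: two-sided Wilcoxon rank-sum test on the absolute
concentrations, BH-FDR tiers at 5%/10%, per-patient mean differences and
fold differences, plus the five derived ratio features. Run
01_simulate_cohort.py first.

Writes results/univariate_day{0,29}.tsv and results/ratio_features.tsv.
"""

from pathlib import Path

from marrownet.data_io import read_concentration_table
from marrownet.univariate import (
    comparison_frame,
    compartment_comparison,
    paired_differences,
    ratio_features,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_concentration_table(OUT / "cohort.tsv")
    for day in (0, 29):
        frame = comparison_frame(compartment_comparison(table, day))
        diffs = paired_differences(table, day)
        frame["mean_difference"] = frame["metabolite"].map(diffs.mean_difference)
        frame["mean_fold"] = frame["metabolite"].map(diffs.mean_fold)
        frame.to_csv(OUT / f"univariate_day{day}.tsv", sep="\t", index=False)
        n10 = int((frame["q"] < 0.10).sum())
        n5 = int((frame["q"] < 0.05).sum())
        print(f"day {day}: {len(frame)} tested, {n10} at pFDR<10% ({n5} at pFDR<5%)")
    ratios = ratio_features(table)
    ratios.reset_index().to_csv(OUT / "ratio_features.tsv", sep="\t", index=False)
    print(f"ratio features: {', '.join(ratios.columns)}")


if __name__ == "__main__":
    main()
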