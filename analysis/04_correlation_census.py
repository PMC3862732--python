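"""Pairwise correlation census and hierarchical clustering.

Computes Pearson correlation matrices (with p-values and per-pair effective
n) for the BM values, PB values and BM−PB differences at day 0, counts
metabolite pairs above the |r| > 0.75 / 0.85 / 0.93 cutoffs, and clusters
the correlation profiles (city-block distance, average linkage). Run
01_simulate_cohort.py first.

Writes results/correlation_*_day0.tsv and results/census_day0.json.
"""

import json
from pathlib import Path

from marrownet.correlation import correlation_matrix, hca_order, threshold_counts
from marrownet.data_io import read_concentration_table
from marrownet.univariate import paired_differences

OUT = Path(__file__).resolve().parent.parent / "results"
CUTOFFS = (0.75, 0.85, 0.93)


def main() -> None:
    table = read_concentration_table(OUT / "cohort.tsv")
    censuses = {}
    for space in ("BM", "PB", "diff"):
        if space == "diff":
            values = paired_differences(table, 0).differences
        else:
            values = table.values_at(space, 0)
        corr = correlation_matrix(values)
        corr.r.to_csv(OUT / f"correlation_{space}_day0.tsv", sep="\t")
        censuses[space] = {str(c): n for c, n in threshold_counts(corr, CUTOFFS).items()}
        order = hca_order(corr).leaf_order
        print(f"{space}: census {censuses[space]}; first clustered leaves: {order[:5]}")
    (OUT / "census_day0.json").write_text(json.dumps(censuses, indent=2) + "\n")


if __name__ == "__main__":
    main()
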