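"""Multilevel PCA and PLS-DA of the paired BM/PB profiles at day 0.

The between-patient variation is removed by the multilevel split; mPCA
summarizes the within-patient compartment contrast, and mPLS-DA classifies
BM vs PB with leave-one-patient-out cross-validation, a within-patient
label-swap permutation test, and ROC sensitivity/specificity. Run
01_simulate_cohort.py first.

Writes results/multilevel_day0.json and mPCA scores.
"""

import json
from pathlib import Path

import pandas as pd

from marrownet.data_io import read_concentration_table
from marrownet.multilevel import mpca, mplsda, permutation_validate
from marrownet.preprocess import glog_transform, suggest_glog_lambda

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table = read_concentration_table(OUT / "cohort.tsv")
    bm = table.values_at("BM", 0)
    pb = table.values_at("PB", 0)
    patients = bm.index.intersection(pb.index)
    stacked = pd.concat([bm.loc[patients], pb.loc[patients]]).dropna(axis=1)
    stacked = glog_transform(stacked, suggest_glog_lambda(stacked))
    subjects = list(patients) * 2
    labels = ["BM"] * len(patients) + ["PB"] * len(patients)

    pca = mpca(stacked.to_numpy(), subjects, k=2)
    plsda = mplsda(stacked.to_numpy(), subjects, labels, n_lv=2)
    perm_p = permutation_validate(stacked.to_numpy(), subjects, labels,
                                  n_perm=99, seed=SEED)

    index = [f"{p}:{c}" for c in ("BM", "PB") for p in patients]
    pd.DataFrame(pca.scores, index=index, columns=["PC1", "PC2"]).to_csv(
        OUT / "mpca_scores_day0.tsv", sep="\t")
    metrics = {
        "mpca_variance_pct": pca.variance_fraction.tolist(),
        "plsda_x_variance_pct": plsda.x_variance_pct.tolist(),
        "plsda_sensitivity_pct": plsda.sensitivity,
        "plsda_specificity_pct": plsda.specificity,
        "permutation_p": perm_p,
    }
    (OUT / "multilevel_day0.json").write_text(json.dumps(metrics, indent=2) + "\n")
    print(f"mPCA variance: {pca.variance_fraction.round(2).tolist()} %")
    print(f"mPLS-DA permutation p = {perm_p:.4g}; "
          f"CV sensitivity {plsda.sensitivity:.0f}%, specificity {plsda.specificity:.0f}%")


if __name__ == "__main__":
    main()
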