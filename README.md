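# marrownet

Paired bone-marrow / peripheral-blood metabolomics analysis: compartment
statistics, multilevel multivariate models, and correlation-network
signatures of the leukemic niche.

## The problem

In pediatric acute lymphoblastic leukemia (ALL) the bone marrow (BM) is
almost completely invaded by blasts at diagnosis, so BM extracellular fluid
sampled at day 0 of induction therapy is a direct readout of the cancer
microenvironment, while peripheral blood (PB) plasma from the same patient
provides the systemic reference. Sampling both compartments again at
remission (day 29) gives a paired design in which every contrast is made
within a patient. `marrownet` implements the full analysis chain for such
paired concentration tables (samples × metabolites, μM, keyed by patient /
compartment / day):

* **Univariate compartment comparisons** — per-metabolite two-sided
  Wilcoxon rank-sum tests of BM vs PB concentrations, Benjamini-Hochberg
  FDR with significance tiers at 5% and 10%, per-patient mean and fold
  differences, and derived ratio features (glutamate/glutamine,
  aspartate/asparagine, choline/creatine, unsaturated/saturated fatty
  acids, glutamine + pyroglutamate).
* **Multilevel models** — the paired matrix splits exactly into
  between-patient means and within-patient deviations; mPCA (SVD of the
  within matrix) and mPLS-DA (NIPALS PLS1 against a ±1 compartment code)
  operate on the within part only, with leave-one-patient-out
  cross-validation, a within-patient label-swap permutation test, and ROC
  sensitivity/specificity at the Youden threshold.
* **Correlation census and clustering** — pairwise-complete Pearson or
  Spearman correlation matrices with p-values from
  t = r·√(n−2)/√(1−r²), counts of pairs with |r| > 0.75 / 0.85 / 0.93, and
  UPGMA clustering of correlation profiles under city-block distance.
* **Network inference** — the core stage. Over the per-patient BM−PB
  difference matrix, every metabolite pair with at least five nonzero
  values becomes a candidate edge carrying Pearson r, its p-value, and the
  Gaussian-copula mutual information MI = −½·ln(1−ρ²) (Spearman ρ by
  default). Edges are admitted at an FDR < 50% Benjamini-Hochberg cutoff on
  the candidate p-value family; edge classes (lipid-lipid, amino-amino,
  other) are compared by Mann-Whitney tests on their edge p-values; ARACNE's
  data-processing inequality removes the weakest edge of every triangle
  (mark-then-sweep, tolerance 0); an FDR < 1% filter retains the strongest
  edges; and connected components with more than three nodes are summarized
  by node/edge counts and edge-averaged R², p, MI.

Because the clinical study's per-patient data are not deposited, a
synthetic cohort generator reproduces the structure the analysis assumes —
10 patients, paired compartments, log-normal concentrations at
physiological μM scales, configurable BM−PB shifts, block-correlated
metabolite groups planted through shared latent factors, and
missing-at-random cells — so every stage is testable end to end.

## Worked example

The numbered drivers under `analysis/` run the study on the default
synthetic cohort (seed 1; a lipid-metabolism block with pairwise r ≈ 0.9
planted in the day-0 BM−PB differences and an amino-acid block at day 29):

```bash
python analysis/01_simulate_cohort.py
python analysis/05_network_enrichment.py
```

prints

```
cohort: 50 samples × 30 metabolites, 76 missing cells → results/cohort.tsv
day 0: 79 edges admitted (p cutoff 0.0896), 7 after ARACNE + FDR<1%; 1 components with >3 nodes
day 29: 33 edges admitted (p cutoff 0.0377), 3 after ARACNE + FDR<1%; 1 components with >3 nodes
day 0 lipid enrichment: one-sided Mann-Whitney p = 5.81e-06
day 29 amino enrichment: one-sided Mann-Whitney p = 0.0954
lipid day 0 vs day 29 (two-sided): p = 1.9e-17
```

Reading: at day 0 the 79 admitted difference-network edges include the
planted lipid block, whose edge p-values are strongly enriched at small
values (one-sided Mann-Whitney p ≈ 6·10⁻⁶); the cross-day comparison of
the lipid candidate-edge families rejects decisively (p ≈ 2·10⁻¹⁷),
i.e. lipid-lipid association is a day-0 signature. This particular
replicate's day-29 amino enrichment is weak (p = 0.095) — single cohorts of
10 patients are noisy, which is why `analysis/06_parameter_recovery.py`
repeats the study over 200 cohorts and reports detection rates (98.5% for
the lipid block, 98.0% for the amino block, 100% for the cross-day
contrast, 2.0% false positives without planted structure).

The same stages are available as a CLI (`marrownet simulate | preprocess |
univariate | mpca | mplsda | correlate | network | report | run-all`) and
as one orchestrated run:

```bash
marrownet run-all --seed 1 --out results/run1
```

which writes per-stage TSV/GraphML/JSON artifacts, a manifest, and a
human-readable `report.md`.

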