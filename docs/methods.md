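# Methods

This note records the models, the parameter choices that matter, and the
design decisions taken where the design was genuinely open.

## Data model

The universal input is a concentration table: samples × metabolites in μM,
each sample keyed by `(patient_id, compartment, day)` with compartment
`BM` (bone marrow extracellular fluid) or `PB` (peripheral blood plasma)
and day ∈ {0, 8, 29} of induction therapy. Missing measurements are
explicit NaN markers, never zeros: the network stage counts *nonzero*
observations, so a metabolite that was measured at zero and one that was
not measured are different things. Metabolite names are matched
case-insensitively after whitespace normalization; name collisions after
normalization are an error rather than a silent merge. A metabolite
annotation assigns each name one of three classes — `lipid_metabolism`,
`amino_acid` (including derivatives and analogues), `other` — in the style
of Human Metabolome Database ontology classes.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
raw spectra. Per metabolite, concentrations are log-normal with the
configured mean and coefficient of variation (default CV 0.3, a typical
between-patient spread for plasma metabolites); BM−PB mean shifts per day
are applied to the BM side. Correlated blocks use one shared latent
Gaussian factor per block on the log scale: a member with target
correlation r gets `z = √r·F + √(1−r)·ε`, so the log-scale pairwise
correlation is exactly r and the raw-scale correlation is the slightly
attenuated log-normal value (≈ 0.896 for r = 0.9 at CV 0.3 — well inside
the ±0.05 the convergence tests allow). Blocks can act on BM values, PB
values, or the per-patient BM−PB differences; in the difference space the
pair is generated as `lower compartment + positive log-normal excess`, with
the excess carrying the block structure, so concentrations stay strictly
positive and the difference is exactly the correlated variable. Negative
target correlations alternate loading signs and are only exactly realized
for two-member blocks. Missingness is completely at random (the study gives
no mechanism to emulate); within-patient BM↔PB covariance beyond the block
structure is not asserted, since the study reports none.

The default panel has 30 named metabolites (10 per class) at physiological
μM scales. The recovery configuration — the study condition for the
headline property — plants a 10-member lipid block (r ≈ 0.9) in the day-0
differences and a 10-member amino block at day 29, with BM−PB mean shifts
of 0.3·mean for the planted class at its active day, 10 patients and 5%
missingness. Creatine and pyroglutamate are not in the default panel, so
two of the five derived ratio features are skipped (with a notice) on
default cohorts; the ratio operations themselves are exercised with
constructed tables.

What passing these tests shows — and does not show: recovery of planted
block correlation demonstrates that the pipeline's statistics detect the
structure they were designed for at the study's n; it does not validate
distributional details of real marrow biofluids (no spectral artifacts,
no batch effects, no informative missingness).

## Preprocessing

Probabilistic quotient normalization divides each sample by the median of
its feature-wise quotients against a reference profile (feature-wise
median sample by default). Binning partitions a positional (ppm-like) axis
into half-open bins `[a, a+w)` anchored at the axis minimum, after
dropping features inside exclusion intervals; aggregation is by **sum**,
conserving integrated intensity (mean would change total signal with
uneven bin occupancy). The generalized log `g(y) = ln((y + √(y²+λ²))/2)`
tends to ln y as λ→0; λ = 0 with zero intensities is rejected rather than
returning −∞. The default λ is the 5th percentile of the nonzero
intensities — small enough to act logarithmically over the informative
range, large enough to stabilize near-zero variance. Spectral peak
alignment is deliberately absent: no spectra exist in this artifact.

## Univariate statistics

Compartments are compared with the two-sided Wilcoxon rank-sum test on
absolute concentrations — the unpaired test, matching the original
analysis, with the paired signed-rank variant available behind
`paired=True` for users who prefer it. The p-value is exact by enumeration
when n₁+n₂ ≤ 20 and tie-free, otherwise a normal approximation with tie
correction and *no* continuity correction (so identical samples give
exactly p = 1). Benjamini-Hochberg adjustment (statsmodels step-up) defines
the significance tiers pFDR < 5% and 5% ≤ pFDR < 10%. Metabolites with
fewer than 3 complete BM/PB pairs are dropped from testing — the
"not detected in all patients" rule; the threshold of 3 is this package's
choice.

## Multilevel models

For paired data the matrix splits exactly: `between` holds patient means,
`within = sample − patient mean`; within rows per patient sum to zero and
the split reconstructs the input to machine precision. mPCA is the SVD of
the column-centered within matrix, variance fractions from squared
singular values; it is invariant to any per-patient offset by
construction. mPLS-DA is a univariate-response NIPALS PLS with sequential
deflation against a ±1 compartment code (cross-checked against sklearn's
PLSRegression in the tests); a class code with no covariance against the
data raises a degenerate-model error rather than returning noise.

Cross-validation leaves one patient out — both of a patient's samples
together, the only scheme that respects pairing. The permutation test
swaps class labels within patient; the identity pattern and the all-flip
pattern are excluded when drawing permutations because both reproduce the
observed pairing partition exactly (PLS-DA is symmetric under global label
reversal), so a perfectly separable cohort attains the floor
p = 1/(n_perm+1). The reference statistic is the Mann-Whitney U of the
cross-validated class scores between the true classes — a rank statistic,
consistent with reporting significance of cross-validated predictive
ability — and p = (1 + #{perm ≥ observed})/(n_perm+1), never zero.

ROC sensitivity/specificity are computed at the Youden-optimal threshold
over interior midpoints of the cross-validated scores, with the
orientation fixed by the class code (no sign flip). If no threshold beats
chance in that fixed orientation — e.g. perfectly anti-ranked scores — the
midpoint between the class median scores is used instead, which reports
the degenerate 0%/0% honestly rather than silently flipping the model's
orientation.

## Correlation census and clustering

Correlations are pairwise-complete: each pair uses the samples where both
metabolites are present, the per-pair effective n is recorded and used in
that pair's p-value, `p = 2·P(t_{n−2} > |r|√(n−2)/√(1−r²))`. Pairs with
fewer than 3 complete observations, and constant vectors, are undefined
(missing) rather than fabricated. Census counts use strict inequality
(|r| > cutoff). Clustering of correlation profiles uses city-block (L1)
distance with average (UPGMA) linkage; the reported leaf order is
canonicalized (children of every merge ordered by smallest leaf label) so
it depends only on the tree, not on input row order.

## Network stage

**Mutual information.** The Gaussian-copula closed form
MI = −½·ln(1−ρ²) nats, even in ρ and strictly increasing in |ρ|; |ρ| ≥ 1 is
clamped to 1−10⁻¹². The relevance stage uses Spearman ρ (robust at n = 10),
the ARACNE stage Pearson r — the two-estimator split the original analysis
used, both exposed.

**Admission.** Candidate edges are all pairs of metabolites with ≥ 5
nonzero non-missing values (in the difference space: nonzero differences).
The BH step-up cutoff at FDR < 50% over the *post-filter* candidate family
gives the admission p-value threshold; admitted edges carry r, p, q, MI,
sign (anticorrelated iff r < 0) and class. An edge is `lipid` or `amino`
only when **both** endpoints belong to that class; mixed edges are
`other`.

**Enrichment.** Within a network, the named class's edge p-values are
compared to all other admitted edges' by a one-sided Mann-Whitney test
(alternative: the class's p-values are stochastically smaller) — this is
the test of the peaks-at-small-p pattern in the smoothed distributions.
Across networks (the same class in the cancer-state vs remission network)
the test is two-sided and uses each network's full candidate-pair family
for the class rather than only admitted edges: each network admits edges at
its own data-driven cutoff, so conditioning both sides on admission would
select small p-values on both sides and bias the comparison toward null.
The Mann-Whitney p is exact whenever the pooled values are tie-free and
n₁·n₂ ≤ 10⁴ (the exact null is cheap there, and the normal approximation
is badly calibrated for very unbalanced families — with 45 vs 1 edges even
a maximally extreme ranking cannot reach p < 0.09 asymptotically while the
exact two-sided p is 2/46); ties or larger families fall back to the
normal approximation with tie correction.

**Smoothed edge-p distributions.** Gaussian kernel density with reflection
at 0 and 1, so all mass stays on the unit interval and the numerical
integral is 1 (tolerance 10⁻³). Bandwidth: Silverman's rule on the edge
p-values, floored at four grid steps for quadrature accuracy, 0.05
fallback at zero spread.

**ARACNE.** Mark-then-sweep data-processing inequality: every triangle
marks its minimum-MI edge(s) — on ties, all minimal edges, guaranteeing a
triangle-free result at tolerance 0 — and all marked edges are removed
simultaneously, so the result is traversal-order independent. A positive
tolerance spares edges within that MI margin of the triangle minimum.

**Retention and components.** After pruning, BH is applied to the
surviving edges' p-values as a family and edges at q ≤ 1% are *retained*
(the visualize-the-strongest-regions reading; the literal drop-the-
significant reading is available via `invert=True`). Connected components
with more than three nodes are reported with node/edge counts and
edge-averaged R², p and MI.

## Study conditions and problem sizes

The parameter-recovery study is 200 cohorts (seeds 1…200 off a base): 10
patients, 30 metabolites (10/10/10 by class), planted blocks at r ≈ 0.9,
5% missingness; detection criteria are one-sided enrichment p < 0.05 for
the planted class at its day and the two-sided cross-day lipid rejection.
The null-calibration study repeats this without blocks. The mPLS-DA null
calibration uses 200 cohorts of 8 subjects × 12 features with zero class
effect and 19 permutations each; the separable checks use 10 subjects × 20
features with a within-pair separation of 10 noise SDs. These sizes keep
the whole suite and the acceptance script at a few minutes on one CPU
while leaving the Monte-Carlo error of every rate well inside its decision
margin.

## Known limitations

* The generator does not emulate spectra, batch effects, platform mixtures
  (MRS vs GC-MS), or informative missingness; conclusions about real
  marrow data need the real data.
* Printed study-level census counts and component statistics (e.g. 179
  pairs at |r| > 0.75; a 32-node component) depend on the undeposited
  per-patient measurements and are treated as magnitude context, not
  reproduction targets.
* The exact Mann-Whitney path requires tie-free values; edge p-values are
  continuous so ties only arise in degenerate constructed inputs, which
  take the asymptotic path.
* Negative-correlation blocks with more than two members cannot make all
  pairs negative (a constraint of any one-factor construction).
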