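"""Paired compartment comparisons.

Per-day bone-marrow vs peripheral-blood contrasts: per-patient differences
and fold differences, two-sided Wilcoxon rank-sum tests on the absolute
concentrations, Benjamini-Hochberg FDR adjustment with significance tiers at
5% and 10%, and the five derived ratio features (glutamate/glutamine,
aspartate/asparagine, choline/creatine, unsaturated/saturated fatty acids,
glutamine + pyroglutamate).

The rank-sum (unpaired) test is applied to the paired compartments, matching
the original analysis; the paired signed-rank alternative is available
behind a flag for users who prefer it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_io import ConcentrationTable, normalize_name

log = logging.getLogger(__name__)

TIER_5 = "pFDR<5%"
TIER_10 = "5%<=pFDR<10%"
TIER_NS = "ns"


@dataclass
class PairedDifferences:
    """Per-patient BM-minus-PB differences at a fixed day (μM)."""

    day: int
    differences: pd.DataFrame  # patients × metabolites; NaN if either side missing
    mean_difference: pd.Series  # mean over complete pairs
    mean_fold: pd.Series  # mean(BM) / mean(PB) over complete pairs


@dataclass
class TestResult:
    metabolite: str
    statistic: float
    p: float
    q: float | None = None
    tier: str | None = None
    n_bm: int = 0
    n_pb: int = 0


def paired_differences(table: ConcentrationTable, day: int) -> PairedDifferences:
    """Per-patient BM − PB differences at ``day``.

    A patient/metabolite difference is missing when either compartment is
    missing. Also reports the per-metabolite mean difference and the mean
    fold difference mean(BM)/mean(PB), both over complete pairs.
    """
    bm = table.values_at("BM", day)
    pb = table.values_at("PB", day)
    patients = bm.index.intersection(pb.index)
    if len(patients) == 0:
        raise ValueError(f"no patients with both compartments at day {day}")
    bm, pb = bm.loc[patients], pb.loc[patients]
    diff = bm - pb
    if diff.notna().sum().sum() == 0:
        raise ValueError(f"no complete BM/PB pairs at day {day}")
    complete = bm.notna() & pb.notna()
    bm_c = bm.where(complete)
    pb_c = pb.where(complete)
    mean_diff = diff.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean_fold = bm_c.mean(axis=0) / pb_c.mean(axis=0)
    return PairedDifferences(int(day), diff, mean_diff, mean_fold)


def rank_sum_test(x, y, paired: bool = False) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    Exact by enumeration when n₁+n₂ ≤ 20 and tie-free, normal approximation
    with tie correction otherwise (no continuity correction, so identical
    samples give p = 1). ``paired=True`` switches to the signed-rank test
    (off by default; the unpaired test is the primary contract).
    """
    x = np.asarray([v for v in np.asarray(x, dtype=float) if not np.isnan(v)])
    y = np.asarray([v for v in np.asarray(y, dtype=float) if not np.isnan(v)])
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty sample after missing-value removal")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test requires equal-length samples")
        res = stats.wilcoxon(x, y)
        return TestResult("", float(res.statistic), float(res.pvalue), n_bm=len(x), n_pb=len(y))
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 20) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult("", float(res.statistic), float(res.pvalue), n_bm=len(x), n_pb=len(y))


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compartment_comparison(
    table: ConcentrationTable, day: int, min_pairs: int = 3, paired: bool = False
) -> list[TestResult]:
    """Per-metabolite BM vs PB rank-sum tests with BH tiers at one day.

    Metabolites with fewer than ``min_pairs`` complete BM/PB pairs (the
    not-detected-in-all-patients case) are dropped from testing.
    """
    bm = table.values_at("BM", day)
    pb = table.values_at("PB", day)
    patients = bm.index.intersection(pb.index)
    if len(patients) == 0:
        raise ValueError(f"no paired patients at day {day}")
    bm, pb = bm.loc[patients], pb.loc[patients]
    results = []
    for metabolite in table.metabolites:
        complete = (bm[metabolite].notna() & pb[metabolite].notna()).sum()
        if complete < min_pairs:
            log.info("skipping %s: only %d complete pairs", metabolite, complete)
            continue
        res = rank_sum_test(bm[metabolite], pb[metabolite], paired=paired)
        res.metabolite = metabolite
        results.append(res)
    if not results:
        raise ValueError("no metabolite has enough complete pairs")
    qs = bh_adjust([r.p for r in results])
    for res, q in zip(results, qs):
        res.q = float(q)
        res.tier = TIER_5 if q < 0.05 else (TIER_10 if q < 0.10 else TIER_NS)
    return results


def comparison_frame(results: list[TestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "statistic": r.statistic,
                "p": r.p,
                "q": r.q,
                "tier": r.tier,
                "n_bm": r.n_bm,
                "n_pb": r.n_pb,
            }
            for r in results
        ]
    )


# Derived ratio features: (output name, numerator names, denominator names).
# A side given as a list is summed over the members present in the panel.
_SATURATED = ("myristic acid", "palmitic acid", "stearic acid", "heptanoic acid")
_UNSATURATED = (
    "palmitoleic acid",
    "cis-9-palmitoleic acid",
    "oleic acid",
    "linoleic acid",
    "linolenic acid",
    "arachidonic acid",
    "eicosadienoic acid",
)

RATIO_FEATURES = (
    ("glutamate_to_glutamine", ("glutamate",), ("glutamine",)),
    ("aspartate_to_asparagine", ("aspartate",), ("asparagine",)),
    ("choline_to_creatine", ("choline",), ("creatine",)),
    ("unsaturated_to_saturated_fatty_acids", _UNSATURATED, _SATURATED),
)
SUM_FEATURES = (("glutamine_plus_pyroglutamate", ("glutamine", "pyroglutamate")),)


def ratio_features(table: ConcentrationTable) -> pd.DataFrame:
    """The five derived ratio/sum columns, where constituents exist.

    A sample's feature is missing when a constituent is missing or a
    denominator is zero (never infinity). Features whose constituents are
    absent from the panel are skipped with a log notice.
    """
    present = {normalize_name(m) for m in table.metabolites}

    def _collect(names):
        cols = [n for n in names if normalize_name(n) in present]
        if not cols:
            return None
        return table.data[cols].sum(axis=1, min_count=len(cols))

    out = {}
    for name, num_names, den_names in RATIO_FEATURES:
        num, den = _collect(num_names), _collect(den_names)
        if num is None or den is None:
            log.info("skipping ratio %s: constituents absent from panel", name)
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = num / den.where(den != 0)
        out[name] = ratio
    for name, names in SUM_FEATURES:
        total = _collect(names)
        if total is None or len([n for n in names if normalize_name(n) in present]) < len(names):
            log.info("skipping sum %s: constituents absent from panel", name)
            continue
        out[name] = total
    return pd.DataFrame(out, index=table.data.index)
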