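"""Paired differences, rank-sum tests, BH adjustment, tiers, ratio features."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import bh_stepup, mann_whitney_enum
from conftest import make_table
from marrownet.panels import REFERENCE_COMPARTMENT_MEANS
from marrownet.univariate import (
    TIER_5,
    bh_adjust,
    compartment_comparison,
    paired_differences,
    rank_sum_test,
    ratio_features,
)


def reference_means_table(day: int):
    """One pseudo-patient holding the published compartment mean profile."""
    col_b, col_p = (f"B{day}", f"P{day}")
    values = {
        met: [row[col_b], row[col_p]]
        for met, row in REFERENCE_COMPARTMENT_MEANS.iterrows()
    }
    return make_table(values, patients=["mean_profile"], days=(day,))


class TestPairedDifferences:
    @pytest.mark.parametrize(
        "metabolite, expected",
        [("urea", 553.85), ("glutamate", 303.71), ("triacylglyceride", 247.33)],
    )
    def test_published_day0_mean_differences(self, metabolite, expected):
        """BM-minus-PB mean differences recomputed from the published
        compartment means match the printed values to 2 decimals."""
        diffs = paired_differences(reference_means_table(0), 0)
        assert diffs.mean_difference[metabolite] == pytest.approx(expected, abs=0.005)

    def test_equal_compartments_give_zero(self):
        table = make_table({"x": [5.0, 5.0, 7.0, 7.0]}, ["p1", "p2"])
        diffs = paired_differences(table, 0)
        assert (diffs.differences["x"] == 0).all()
        assert diffs.mean_fold["x"] == pytest.approx(1.0)

    def test_mean_difference_equals_difference_of_means_when_complete(self, rng):
        values = {f"m{i}": rng.lognormal(2, 0.5, 8) for i in range(4)}
        table = make_table(values, [f"p{i}" for i in range(4)])
        diffs = paired_differences(table, 0)
        bm = table.values_at("BM", 0).mean()
        pb = table.values_at("PB", 0).mean()
        pd.testing.assert_series_equal(diffs.mean_difference, bm - pb)

    def test_missing_side_makes_difference_missing(self):
        table = make_table({"x": [5.0, np.nan, 7.0, 6.0]}, ["p1", "p2"])
        diffs = paired_differences(table, 0)
        assert np.isnan(diffs.differences.loc["p1", "x"])
        assert diffs.differences.loc["p2", "x"] == 1.0

    def test_no_pairs_is_error(self):
        table = make_table({"x": [1.0, 2.0]}, ["p1"], compartments=("BM",), days=(0, 29))
        with pytest.raises(ValueError):
            paired_differences(table, 0)


class TestRankSum:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [4, 5, 6], 0.1),       # 2/20 by enumeration
            ([1, 2], [3, 4], 1 / 3),            # 2/6
            ([1, 2, 3], [1, 2, 3], 1.0),        # identical multisets
        ],
    )
    def test_exact_worked_examples(self, x, y, expected):
        assert rank_sum_test(x, y).p == pytest.approx(expected)

    def test_matches_enumeration_oracle_all_small_sizes(self, rng):
        """Exact p equals full enumeration for every split with n1+n2 ≤ 10."""
        for n1 in range(1, 10):
            for n2 in range(1, 11 - n1):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                assert rank_sum_test(x, y).p == pytest.approx(
                    mann_whitney_enum(x, y, "two-sided"), abs=1e-12
                ), (n1, n2)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_missing_values_removed_first(self):
        res = rank_sum_test([1, 2, np.nan], [3, 4])
        assert res.n_bm == 2 and res.n_pb == 2


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.04], [0.02, 0.04]),
            ([0.005, 0.1, 0.9], [0.015, 0.15, 0.9]),
            ([0.3, 0.3, 0.3], [0.3, 0.3, 0.3]),
        ],
    )
    def test_worked_examples(self, p, expected):
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
                 min_size=1, max_size=30)
    )
    def test_matches_stepup_definition(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_stepup(p), rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCompartmentComparison:
    def test_large_shift_lands_in_top_tier(self, rng):
        values = {}
        base = rng.lognormal(3, 0.1, 20)  # 10 patients × 2 compartments
        values["shifted"] = np.where(np.arange(20) % 2 == 0, base * 20, base)
        for i in range(5):
            values[f"null{i}"] = rng.lognormal(3, 0.1, 20)
        table = make_table(values, [f"p{i}" for i in range(10)])
        results = {r.metabolite: r for r in compartment_comparison(table, 0)}
        assert results["shifted"].tier == TIER_5

    def test_single_metabolite_q_equals_p(self, rng):
        table = make_table({"only": rng.lognormal(2, 0.3, 8)}, [f"p{i}" for i in range(4)])
        (result,) = compartment_comparison(table, 0)
        assert result.q == pytest.approx(result.p)

    def test_sparse_metabolite_dropped(self, rng):
        sparse = rng.lognormal(2, 0.3, 8)
        sparse[[0, 2, 4]] = np.nan  # < 3 complete pairs
        table = make_table(
            {"dense": rng.lognormal(2, 0.3, 8), "sparse": sparse},
            [f"p{i}" for i in range(4)],
        )
        tested = [r.metabolite for r in compartment_comparison(table, 0)]
        assert tested == ["dense"]

    def test_fdr_calibrated_under_null(self, rng):
        """Fraction of null metabolites reaching pFDR<10% averages ≤ 0.10."""
        rates = []
        for _ in range(60):
            values = {f"m{i}": rng.lognormal(2, 0.3, 12) for i in range(40)}
            table = make_table(values, [f"p{i}" for i in range(6)])
            results = compartment_comparison(table, 0)
            rates.append(np.mean([r.q < 0.10 for r in results]))
        assert np.mean(rates) <= 0.10 + 0.02


class TestRatioFeatures:
    def test_ratio_and_sum_arithmetic(self):
        table = make_table(
            {
                "glutamate": [400.0, 100.0],
                "glutamine": [200.0, 352.78],
                "pyroglutamate": [50.0, 100.0],
            },
            ["p1"],
        )
        out = ratio_features(table)
        assert out["glutamate_to_glutamine"].iloc[0] == pytest.approx(2.0)
        assert out["glutamine_plus_pyroglutamate"].iloc[1] == pytest.approx(452.78)

    def test_zero_denominator_is_missing(self):
        table = make_table({"glutamate": [4.0, 4.0], "glutamine": [0.0, 2.0]}, ["p1"])
        out = ratio_features(table)
        assert np.isnan(out["glutamate_to_glutamine"].iloc[0])
        assert np.isfinite(out["glutamate_to_glutamine"].iloc[1])

    def test_absent_constituents_skip_feature(self, small_table):
        out = ratio_features(small_table)
        assert "aspartate_to_asparagine" not in out.columns
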