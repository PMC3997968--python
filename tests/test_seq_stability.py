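"""Normalization, slope-1 residual fold changes, stability filtering, Venn."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from stabref import (
    RawCountMatrix,
    filter_stable,
    fit_slope1,
    intersect_conditions,
    normalize_counts,
    pairwise_fold_change,
    percent_variation,
    tier_by_abundance,
)


class TestNormalize:
    def test_single_sample_is_identity(self):
        raw = RawCountMatrix(pd.DataFrame({"s": [100, 900]}, index=["a", "b"]))
        norm = normalize_counts(raw)
        assert norm.linear["s"].tolist() == [100.0, 900.0]

    def test_hand_computed_scaling(self, toy_counts):
        # totals 1000 and 2000, mean 1500: x = (100, 300) -> (150, 225)
        norm = normalize_counts(toy_counts)
        assert norm.linear.loc["x"].tolist() == [150.0, 225.0]
        # per-sample totals all equal the mean raw total
        np.testing.assert_allclose(norm.linear.sum(axis=0), 1500.0)

    def test_log2_layer_uses_pseudocount(self):
        raw = RawCountMatrix(pd.DataFrame({"s": [0.0, 90.0]}, index=["a", "b"]))
        norm = normalize_counts(raw, pseudocount=10)
        assert norm.log2.loc["a", "s"] == pytest.approx(np.log2(10), abs=1e-12)

    def test_idempotent(self, toy_counts):
        once = normalize_counts(toy_counts)
        twice = normalize_counts(RawCountMatrix(once.linear))
        pd.testing.assert_frame_equal(once.linear, twice.linear)

    def test_per_sample_rescaling_only_moves_the_global_scale(self, toy_counts):
        # rescaling one sample's library cancels within each sample; the
        # x(mean total) step leaves a single global factor
        norm = normalize_counts(toy_counts)
        scaled = toy_counts.counts.copy()
        scaled["s2"] *= 7.3
        renorm = normalize_counts(RawCountMatrix(scaled))
        factor = scaled.sum(axis=0).mean() / toy_counts.counts.sum(axis=0).mean()
        np.testing.assert_allclose(renorm.linear, norm.linear * factor, rtol=1e-12)

    def test_zero_total_sample_named_in_error(self):
        raw = pd.DataFrame({"good": [1, 2], "empty": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            normalize_counts(RawCountMatrix(raw))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            RawCountMatrix(pd.DataFrame({"s": [-1, 2]}, index=["a", "b"]))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            RawCountMatrix(pd.DataFrame({"s": [1, 2]}, index=["a", "a"]))


class TestSlopeOneFit:
    @pytest.mark.parametrize(
        "x, y, intercept, residuals",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 0.0, [0.0, 0.0, 0.0]),
            ([1.0, 2.0, 3.0], [2.0, 3.0, 4.0], 1.0, [0.0, 0.0, 0.0]),
            ([0.0, 1.0, 2.0], [0.0, 1.0, 4.0], 2 / 3, [-2 / 3, -2 / 3, 4 / 3]),
        ],
    )
    def test_closed_form(self, x, y, intercept, residuals):
        fit = fit_slope1(x, y)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        np.testing.assert_allclose(fit.residuals, residuals, atol=1e-12)

    def test_intercept_minimizes_sum_of_squares(self, rng):
        # numerical oracle: scan intercepts around the analytic optimum
        x = rng.normal(size=30)
        y = x + 0.4 + rng.normal(scale=0.3, size=30)
        fit = fit_slope1(x, y)
        sse = ((y - x - fit.intercept) ** 2).sum()
        for b in fit.intercept + np.linspace(-0.5, 0.5, 41):
            assert sse <= ((y - x - b) ** 2).sum() + 1e-12

    def test_residuals_sum_to_zero(self, rng):
        fit = fit_slope1(rng.normal(size=50), rng.normal(size=50))
        assert fit.residuals.sum() == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_moves_intercept_not_residuals(self, rng):
        x, y = rng.normal(size=20), rng.normal(size=20)
        base, shifted = fit_slope1(x, y), fit_slope1(x, y + 5.0)
        assert shifted.intercept == pytest.approx(base.intercept + 5.0)
        np.testing.assert_allclose(shifted.residuals, base.residuals, atol=1e-12)

    def test_length_mismatch_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="length"):
            fit_slope1([1.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="finite"):
            fit_slope1([1.0, np.nan], [1.0, 2.0])


class TestPercentVariation:
    @pytest.mark.parametrize(
        "residual, expected",
        [(0.0, 0.0), (1.0, 100.0), (np.log2(1.07), 7.0), (-np.log2(1.07), 7.0)],
    )
    def test_definition(self, residual, expected):
        v = percent_variation(np.array([residual]))
        assert v.iloc[0] == pytest.approx(expected, abs=1e-9)

    def test_round_trip_at_threshold(self):
        # residual implied by 7% inverts back to 7%
        r = np.log2(1 + 7 / 100)
        assert percent_variation(np.array([r])).iloc[0] == pytest.approx(7.0)

    def test_invariant_to_library_size_ratio(self, toy_counts):
        # exact with pseudocount 0, where a library-size ratio is a pure
        # log2 shift absorbed by the slope-1 intercept
        norm = normalize_counts(toy_counts, pseudocount=0)
        v = percent_variation(pairwise_fold_change(norm, "s1", "s2"))
        scaled = toy_counts.counts.copy()
        scaled["s2"] *= 3.0
        v2 = percent_variation(
            pairwise_fold_change(
                normalize_counts(RawCountMatrix(scaled), pseudocount=0), "s1", "s2"
            )
        )
        np.testing.assert_allclose(v, v2, atol=1e-9)

    def test_pseudocount_damps_but_barely_moves_abundant_variation(self, toy_counts):
        # with the default pseudocount of 10, invariance to library-size
        # ratio is approximate; at read counts in the tens of thousands
        # the effect is well under a tenth of a percentage point
        abundant = RawCountMatrix(toy_counts.counts * 100)
        norm = normalize_counts(abundant)
        v = percent_variation(pairwise_fold_change(norm, "s1", "s2"))
        scaled = abundant.counts.copy()
        scaled["s2"] *= 3.0
        v2 = percent_variation(
            pairwise_fold_change(normalize_counts(RawCountMatrix(scaled)), "s1", "s2")
        )
        np.testing.assert_allclose(v, v2, atol=0.1)


class TestFilterStable:
    def test_toy_example_direct_metric(self, norm_from_linear):
        # A constant 1000/1000, B 1000 -> 1200: direct variation 0% vs 16.7%
        norm = norm_from_linear({"s1": [1000.0, 1000.0], "s2": [1000.0, 1200.0]}, ["A", "B"])
        report = filter_stable(norm, [("s1", "s2")], variation_metric="direct")
        assert report.passed == {"A"}
        assert report.variation_pct["B"] == pytest.approx(200 / 12, abs=1e-9)

    def test_toy_example_residual_metric_splits_two_gene_shift(self, norm_from_linear):
        # with only two genes the intercept absorbs half of B's shift, so
        # both genes carry the same residual-implied variation (9.46%)
        norm = norm_from_linear({"s1": [1000.0, 1000.0], "s2": [1000.0, 1200.0]}, ["A", "B"])
        report = filter_stable(norm, [("s1", "s2")], variation_metric="residual")
        half_shift = np.log2(1210 / 1010) / 2  # pseudocount 10 in the log2 layer
        expected = (2**half_shift - 1) * 100
        np.testing.assert_allclose(report.variation_pct, [expected, expected], atol=1e-9)
        assert report.passed == set()

    def test_abundance_floor_excludes_flat_but_rare_mirna(self, norm_from_linear):
        norm = norm_from_linear({"s1": [400.0, 4000.0], "s2": [400.0, 4000.0]}, ["low", "high"])
        report = filter_stable(norm, [("s1", "s2")])
        assert report.passed == {"high"}
        assert report.variation_pct["low"] == pytest.approx(0.0, abs=1e-9)

    def test_floor_must_hold_in_every_sample(self, norm_from_linear):
        norm = norm_from_linear(
            {"s1": [600.0, 600.0], "s2": [450.0, 600.0], "s3": [600.0, 600.0]},
            ["dips", "steady"],
        )
        report = filter_stable(
            norm, [("s1", "s2"), ("s1", "s3")], var_threshold_pct=np.inf
        )
        assert "steady" in report.passed and "dips" not in report.passed

    def test_infinite_threshold_passes_all_zero_threshold_exact_only(self, rng):
        counts = pd.DataFrame(
            rng.integers(600, 5000, (10, 2)).astype(float),
            index=[f"m{i}" for i in range(10)],
            columns=["a", "b"],
        )
        norm = normalize_counts(RawCountMatrix(counts))
        everything = filter_stable(norm, [("a", "b")], var_threshold_pct=np.inf, min_reads=0)
        assert everything.passed == set(norm.mirna_ids)
        strict = filter_stable(norm, [("a", "b")], var_threshold_pct=0.0, min_reads=0)
        res = pairwise_fold_change(norm, "a", "b").residuals
        assert strict.passed == set(res.index[res == 0.0])

    def test_max_over_group_comparisons(self, norm_from_linear):
        norm = norm_from_linear(
            {"c": [1000.0], "mild": [1030.0], "wild": [1500.0]}, ["m"]
        )
        report = filter_stable(
            norm, [("c", "mild"), ("c", "wild")], variation_metric="direct"
        )
        assert report.variation_pct["m"] == pytest.approx(500 / 15, abs=1e-9)

    def test_empty_group_and_unknown_sample_rejected(self, norm_from_linear):
        norm = norm_from_linear({"s1": [1.0], "s2": [2.0]}, ["m"])
        with pytest.raises(ValueError, match="empty"):
            filter_stable(norm, [])
        with pytest.raises(KeyError, match="nope"):
            filter_stable(norm, [("s1", "nope")])


class TestIntersectConditions:
    def test_simple_intersection(self):
        inter = intersect_conditions({"c1": {"A", "B"}, "c2": {"B", "C"}})
        assert inter.all_conditions == {"B"}
        assert inter.venn_partition["c1"] == {"A"}
        assert inter.venn_partition["c2"] == {"C"}
        assert inter.venn_partition["c1+c2"] == {"B"}

    def test_identical_sets(self):
        inter = intersect_conditions({"x": {"A", "B"}, "y": {"A", "B"}})
        assert inter.all_conditions == {"A", "B"}
        assert inter.venn_partition["x"] == set() and inter.venn_partition["y"] == set()

    def test_fewer_than_two_conditions_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            intersect_conditions({"only": {"A"}})

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        sets=hst.lists(
            hst.sets(hst.sampled_from("abcdefgh")), min_size=2, max_size=4
        )
    )
    def test_venn_partition_matches_membership_profile_oracle(self, sets):
        """Brute-force oracle: each element belongs to exactly the region
        named by the conditions containing it; regions are disjoint and
        union to the union of inputs."""
        reports = {f"c{i}": s for i, s in enumerate(sets)}
        inter = intersect_conditions(reports)
        universe = set().union(*sets)
        # disjointness + coverage
        regions = list(inter.venn_partition.values())
        assert set().union(*regions, set()) == universe
        for r1, r2 in itertools.combinations(regions, 2):
            assert not (r1 & r2)
        # element-wise oracle
        for el in universe:
            profile = "+".join(sorted(c for c, s in reports.items() if el in s))
            assert el in inter.venn_partition[profile]


class TestTierByAbundance:
    def test_reported_tier_examples(self, norm_from_linear):
        # read counts at which candidates were called low/medium/high
        norm = norm_from_linear(
            {"s": [636.433, 6457.365, 163324.299]}, ["lo", "mid", "hi"]
        )
        tiers = tier_by_abundance(norm, ["lo", "mid", "hi"], boundaries=(2000, 100000))
        assert tiers == {"low": {"lo"}, "medium": {"mid"}, "high": {"hi"}}

    def test_all_below_lower_boundary(self, norm_from_linear):
        norm = norm_from_linear({"s": [10.0, 20.0]}, ["a", "b"])
        tiers = tier_by_abundance(norm, ["a", "b"], boundaries=(2000, 100000))
        assert tiers["low"] == {"a", "b"} and not tiers["medium"] and not tiers["high"]

    def test_boundary_value_goes_to_higher_tier(self, norm_from_linear):
        norm = norm_from_linear({"s": [2000.0, 100000.0]}, ["edge_lo", "edge_hi"])
        tiers = tier_by_abundance(norm, ["edge_lo", "edge_hi"], boundaries=(2000, 100000))
        assert "edge_lo" in tiers["medium"] and "edge_hi" in tiers["high"]

    def test_unknown_candidate_rejected(self, norm_from_linear):
        norm = norm_from_linear({"s": [1.0]}, ["a"])
        with pytest.raises(KeyError, match="ghost"):
            tier_by_abundance(norm, ["ghost"])


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    counts=hst.lists(
        hst.tuples(
            hst.integers(min_value=1, max_value=10**6),
            hst.integers(min_value=1, max_value=10**6),
        ),
        min_size=2,
        max_size=12,
    ),
    scale=hst.floats(min_value=0.01, max_value=100.0),
)
def test_normalization_scale_invariance_property(counts, scale):
    """Multiplying one sample's counts by any positive constant leaves the
    normalized linear matrix unchanged up to the single global factor
    introduced by the x(mean total) step, and leaves each sample's
    within-sample profile exactly unchanged."""
    df = pd.DataFrame(counts, columns=["a", "b"], dtype=float)
    df.index = [f"m{i}" for i in range(len(df))]
    base = normalize_counts(RawCountMatrix(df)).linear
    scaled_df = df.copy()
    scaled_df["b"] *= scale
    scaled = normalize_counts(RawCountMatrix(scaled_df)).linear
    factor = scaled_df.sum(axis=0).mean() / df.sum(axis=0).mean()
    np.testing.assert_allclose(base * factor, scaled, rtol=1e-9)
    np.testing.assert_allclose(
        base / base.sum(axis=0), scaled / scaled.sum(axis=0), rtol=1e-9
    )
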