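import itertools
import math

import numpy as np
import pytest

import xdosage as xd
from xdosage.io import DataError
from xdosage.ratios import ALL_GENES, bootstrap_replicates

from conftest import build_matrix

X2A2 = {"x1": "X", "x2": "X", "a1": "1", "a2": "2"}


class TestPointRatio:
    def test_equal_means_give_one(self):
        m = build_matrix({"x1": [2], "x2": [2], "a1": [1], "a2": [3]}, X2A2)
        assert xd.xaa_ratio(m, 0.0).ratio == 1.0

    def test_single_x_gene(self):
        m = build_matrix({"x1": [4], "a1": [1], "a2": [3]},
                         {"x1": "X", "a1": "1", "a2": "2"})
        assert xd.xaa_ratio(m, 0.0).ratio == 2.0

    def test_filter_applies_before_means(self):
        # X {0.5, 4} filtered at 1 leaves {4}; A {2, 2} untouched -> 2.0
        m = build_matrix({"x1": [0.5], "x2": [4], "a1": [2], "a2": [2]}, X2A2)
        est = xd.xaa_ratio(m, 1.0)
        assert (est.ratio, est.n_x, est.n_a) == (2.0, 1, 2)

    def test_empty_class_is_error_naming_context(self):
        m = build_matrix({"x1": [0.5], "a1": [2]}, {"x1": "X", "a1": "1"})
        with pytest.raises(DataError, match="cutoff 1.0"):
            xd.xaa_ratio(m, 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = {f"g{i}": [v] for i, v in enumerate(rng.lognormal(1, 1, 60))}
        chroms = {g: ("X" if i % 5 == 0 else "1") for i, g in enumerate(vals)}
        m = build_matrix(vals, chroms)
        k = 37.5
        m_scaled = xd.ExpressionMatrix(m.values * k, m.annotation, m.samples)
        assert xd.xaa_ratio(m_scaled, 0.0).ratio == pytest.approx(
            xd.xaa_ratio(m, 0.0).ratio, rel=1e-12
        )


class TestBootstrap:
    def test_degenerate_autosomes_give_zero_width_ci(self):
        m = build_matrix({"x1": [2], "x2": [4], "a1": [3], "a2": [3], "a3": [3]},
                         {"x1": "X", "x2": "X", "a1": "1", "a2": "1", "a3": "2"})
        est = xd.bootstrap_xaa(m, 0.0, n_boot=200, seed=0)
        assert est.ci_low == est.ci_high == 1.0

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(2)
        vals = {f"g{i}": [v] for i, v in enumerate(rng.lognormal(1, 1, 80))}
        chroms = {g: ("X" if i < 10 else "1") for i, g in enumerate(vals)}
        m = build_matrix(vals, chroms)
        a = xd.bootstrap_xaa(m, 0.0, n_boot=500, seed=42)
        b = xd.bootstrap_xaa(m, 0.0, n_boot=500, seed=42)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_narrow_ci_nested_in_wide(self):
        rng = np.random.default_rng(3)
        vals = {f"g{i}": [v] for i, v in enumerate(rng.lognormal(1, 1, 100))}
        chroms = {g: ("X" if i < 15 else "1") for i, g in enumerate(vals)}
        m = build_matrix(vals, chroms)
        c90 = xd.bootstrap_xaa(m, 0.0, level=0.90, n_boot=400, seed=9)
        c99 = xd.bootstrap_xaa(m, 0.0, level=0.99, n_boot=400, seed=9)
        assert c99.ci_low <= c90.ci_low and c90.ci_high <= c99.ci_high

    def test_ci_width_follows_finite_population_correction(self):
        # subsampling without replacement: replicate variance carries the
        # factor (N-n)/(N-1), so widening the autosomal pool (same value
        # distribution) widens the CI toward the with-replacement limit
        rng = np.random.default_rng(4)
        x = rng.lognormal(1, 1, 20)
        a_small = rng.lognormal(1, 1, 40)
        a_large = np.tile(a_small, 50)  # same distribution, N x50

        def width(a, seed):
            reps = bootstrap_replicates(x, a, 400, seed)
            return np.percentile(reps, 95) - np.percentile(reps, 5)

        small = np.mean([width(a_small, s) for s in range(5)])
        large = np.mean([width(a_large, s) for s in range(5)])
        wr = np.mean([
            np.percentile(r := bootstrap_replicates(x, a_small, 400, s,
                                                    with_replacement=True), 95)
            - np.percentile(r, 5)
            for s in range(5)
        ])
        assert small < large <= wr * 1.1

    def test_oversampling_without_replacement_errors(self):
        with pytest.raises(DataError, match="without replacement"):
            bootstrap_replicates(np.ones(5), np.ones(3), 10, 0)

    def test_replicate_support_matches_subset_enumeration(self):
        # C(6,2)=15 possible autosomal subsets: bootstrap support = enumeration
        x = np.array([2.0, 6.0])
        a = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 13.0])
        reps = bootstrap_replicates(x, a, n_boot=3000, seed=7)
        expected = {
            round(x.mean() / np.mean(pair), 12)
            for pair in itertools.combinations(a, 2)
        }
        assert {round(r, 12) for r in reps} == expected


class TestCutoffSeries:
    def test_no_filterable_values_gives_identical_entries(self):
        m = build_matrix({"x1": [3], "a1": [2], "a2": [4]},
                         {"x1": "X", "a1": "1", "a2": "2"})
        series = xd.ratio_cutoff_series(m, [0.0, 0.5, 1.0])
        ratios = {e.ratio for e in series}
        assert len(ratios) == 1

    def test_cutoff_removing_all_x_recorded_missing(self):
        m = build_matrix({"x1": [0.5], "x2": [0.5], "a1": [2], "a2": [2]}, X2A2)
        series = xd.ratio_cutoff_series(m, [0.0, 1.0], include_all_genes=False)
        assert series[0].ratio == 0.25
        assert series[1] is None

    def test_sentinel_differs_from_zero_cutoff_iff_zeros_present(self):
        with_zero = build_matrix({"x1": [2], "x2": [0], "a1": [2], "a2": [2]}, X2A2)
        series = xd.ratio_cutoff_series(with_zero, [0.0])
        assert series[0].n_x == 2 and series[1].n_x == 1
        no_zero = build_matrix({"x1": [2], "x2": [1], "a1": [2], "a2": [2]}, X2A2)
        series = xd.ratio_cutoff_series(no_zero, [0.0])
        assert series[0].ratio == series[1].ratio

    def test_unsorted_cutoffs_rejected(self):
        m = build_matrix({"x1": [2], "a1": [2]}, {"x1": "X", "a1": "1"})
        with pytest.raises(DataError, match="ascending"):
            xd.ratio_cutoff_series(m, [1.0, 0.0])


class TestHkgRatios:
    def test_common_value_hkgs_give_unity(self):
        m = build_matrix(
            {"x1": [6], "x2": [2], "xh": [5], "a1": [3], "ah1": [5], "ah2": [5]},
            {"x1": "X", "x2": "X", "xh": "X", "a1": "1", "ah1": "1", "ah2": "2"},
        )
        x_to_ahkg, xhkg_to_ahkg = xd.hkg_ratios(m, ["ah1", "ah2"], ["xh"], cutoff=0.0)
        assert xhkg_to_ahkg == 1.0
        # all X genes (incl. the X HKG): mean(6,2,5)/5
        assert x_to_ahkg == pytest.approx(13 / 3 / 5)

    def test_disjoint_hkg_set_is_error(self):
        m = build_matrix({"x1": [2], "a1": [2]}, {"x1": "X", "a1": "1"})
        with pytest.raises(DataError, match="AHKG"):
            xd.hkg_ratios(m, ["nope"], ["x1"], cutoff=0.0)


class TestUnexpressedFraction:
    def test_balanced_fractions(self):
        m = build_matrix(
            {"x1": [0], "x2": [2], "a1": [0], "a2": [0], "a3": [2], "a4": [2]},
            {"x1": "X", "x2": "X", "a1": "1", "a2": "1", "a3": "2", "a4": "2"},
        )
        out = xd.unexpressed_fraction(m, 0.0)
        assert out["fraction"].tolist() == [0.5, 0.5]
        assert out["fold_x_over_a"].iloc[0] == 1.0

    def test_all_expressed_fold_missing(self):
        m = build_matrix({"x1": [2], "a1": [2]}, {"x1": "X", "a1": "1"})
        out = xd.unexpressed_fraction(m, 0.0)
        assert out["fraction"].tolist() == [0.0, 0.0]
        assert math.isnan(out["fold_x_over_a"].iloc[0])


class TestCombineSources:
    def test_mean_and_single_source(self):
        combined = xd.combine_ratio_sources(
            {"liver": [0.4, 0.6], "brain": [1.3], "t": [1, 1, 1]}
        )
        assert combined == {"liver": 0.5, "brain": 1.3, "t": 1.0}

    def test_empty_source_list_is_error(self):
        with pytest.raises(DataError, match="liver"):
            xd.combine_ratio_sources({"liver": []})
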