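import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import xdosage as xd
from xdosage.io import DataError
from xdosage.stages import _spearman_rho, spearman_exact_pvalue

from conftest import build_matrix, sample_sheet


def brute_force_spearman_p(x, y):
    """Independent permutation oracle: two-sided p over all y permutations."""
    rx = stats.rankdata(x)
    obs = abs(_spearman_rho(rx, stats.rankdata(y)))
    count = total = 0
    for perm in itertools.permutations(y):
        rho = _spearman_rho(rx, stats.rankdata(perm))
        total += 1
        if not math.isnan(rho) and abs(rho) >= obs - 1e-12:
            count += 1
    return count / total


class TestStageCorrelation:
    def _matrix(self, rows, ranks):
        samples = sample_sheet(["liver"] * len(ranks), ranks)
        chroms = {g: "1" for g in rows}
        return build_matrix(rows, chroms, samples)

    def test_monotone_increase_gives_rho_one(self):
        m = self._matrix({"g1": [1, 2, 3, 4, 5]}, [1, 2, 3, 4, 5])
        res = xd.stage_correlation(m, "liver")
        assert res.loc["g1", "rho"] == 1.0
        assert res.loc["g1", "p"] == pytest.approx(2 / math.factorial(5))

    def test_hand_computed_rho(self):
        # expression (3,1,2) against ranks (1,2,3): rho = -0.5
        m = self._matrix({"g1": [3, 1, 2, 5]}, [1, 2, 3, 4])
        res = xd.stage_correlation(m, "liver")
        # recompute on the 3-point example directly
        assert _spearman_rho(np.array([3.0, 1.0, 2.0]),
                             np.array([1.0, 2.0, 3.0])) == -0.5
        assert -1 <= res.loc["g1", "rho"] <= 1

    def test_exact_p_matches_permutation_enumeration(self):
        rng = np.random.default_rng(11)
        ranks = [1, 2, 3, 4, 5]
        for _ in range(5):
            expr = rng.lognormal(0, 1, 5)
            p = spearman_exact_pvalue(stats.rankdata(expr), stats.rankdata(ranks))
            assert p == pytest.approx(brute_force_spearman_p(expr, ranks), abs=1e-12)

    def test_exact_p_with_tied_stages(self):
        # replicates share a stage rank; oracle must agree under ties
        ranks = [1, 1, 2, 2, 3, 3]
        expr = [0.5, 0.2, 1.0, 3.0, 2.0, 5.0]
        p = spearman_exact_pvalue(stats.rankdata(expr), stats.rankdata(ranks))
        assert p == pytest.approx(brute_force_spearman_p(expr, ranks), abs=1e-12)

    def test_constant_gene_reported_missing(self):
        m = self._matrix({"g1": [2, 2, 2, 2], "g2": [1, 2, 3, 4]}, [1, 2, 3, 4])
        res = xd.stage_correlation(m, "liver")
        assert math.isnan(res.loc["g1", "rho"])
        assert res.loc["g2", "rho"] == 1.0

    def test_too_few_samples_is_error(self):
        m = self._matrix({"g1": [1, 2, 3]}, [1, 2, 3])
        with pytest.raises(DataError, match="samples"):
            xd.stage_correlation(m, "liver")

    def test_invariant_to_monotone_transform(self):
        ranks = [1, 2, 3, 4, 5, 6]
        rng = np.random.default_rng(3)
        expr = rng.lognormal(0, 1, 6)
        m1 = self._matrix({"g1": list(expr)}, ranks)
        m2 = self._matrix({"g1": list(np.exp(expr))}, ranks)
        r1 = xd.stage_correlation(m1, "liver").loc["g1"]
        r2 = xd.stage_correlation(m2, "liver").loc["g1"]
        assert r1["rho"] == r2["rho"] and r1["p"] == r2["p"]

    def test_t_approximation_matches_scipy_for_large_n(self):
        n = 20
        rng = np.random.default_rng(7)
        ranks = list(range(1, n + 1))
        expr = rng.lognormal(0, 1, n)
        m = self._matrix({"g1": list(expr)}, ranks)
        res = xd.stage_correlation(m, "liver").loc["g1"]
        rho, p = stats.spearmanr(expr, ranks)
        assert res["rho"] == pytest.approx(rho, abs=1e-12)
        assert res["p"] == pytest.approx(p, rel=1e-9)


class TestClassification:
    def _results(self, rows):
        return pd.DataFrame(rows, columns=["rho", "p"],
                            index=[f"g{i}" for i in range(len(rows))])

    @pytest.mark.parametrize(
        "rho,p,expected",
        [(0.9, 0.01, "positive"), (0.9, 0.2, "none"), (-0.85, 0.03, "negative")],
    )
    def test_threshold_rules(self, rho, p, expected):
        pos, neg = xd.classify_stage_correlated(self._results([(rho, p)]))
        got = "positive" if "g0" in pos else "negative" if "g0" in neg else "none"
        assert got == expected

    def test_sets_disjoint_and_nested_across_thresholds(self):
        rng = np.random.default_rng(5)
        rows = list(zip(rng.uniform(-1, 1, 200), rng.uniform(0, 0.1, 200)))
        res = self._results(rows)
        prev_pos = prev_neg = None
        for thr in (0.5, 0.6, 0.7, 0.8, 0.9):
            pos, neg = xd.classify_stage_correlated(res, thr)
            assert set(pos).isdisjoint(neg)
            if prev_pos is not None:
                assert set(pos) <= set(prev_pos) and set(neg) <= set(prev_neg)
            prev_pos, prev_neg = pos, neg


class TestThresholdSweep:
    def test_baseline_is_x_share_of_scored_genes(self, make_annotation):
        ann = make_annotation({f"g{i}": ("X" if i < 10 else "1") for i in range(100)})
        rng = np.random.default_rng(9)
        res = pd.DataFrame(
            {"rho": rng.uniform(-1, 1, 100), "p": rng.uniform(0, 0.04, 100)},
            index=[f"g{i}" for i in range(100)],
        )
        sweep = xd.xlinked_fraction_by_threshold(res, ann, thresholds=[0.5])
        assert (sweep["baseline_fraction_x"] == 0.10).all()

    def test_no_x_genes_gives_zero_fractions(self, make_annotation):
        ann = make_annotation({f"g{i}": "1" for i in range(20)})
        res = pd.DataFrame(
            {"rho": [0.95] * 20, "p": [0.001] * 20},
            index=[f"g{i}" for i in range(20)],
        )
        sweep = xd.xlinked_fraction_by_threshold(res, ann, thresholds=[0.5, 0.9])
        pos = sweep[sweep["sign"] == "positive"]
        assert (pos["fraction_x"] == 0.0).all()

    def test_x_enriched_trends_exceed_baseline(self):
        params = xd.SimulationParams(
            n_autosomal_genes=900, n_x_genes=100, n_tissues=1, n_stages=10,
            frac_stage_pos_x=0.3, frac_stage_pos_a=0.05, seed=13,
        )
        ann = xd.simulate_genome(params)
        m = xd.simulate_expression(ann, params)
        res = xd.stage_correlation(m, params.tissues[0])
        sweep = xd.xlinked_fraction_by_threshold(res, ann, thresholds=[0.8])
        pos = sweep[(sweep["sign"] == "positive")].iloc[0]
        assert pos["fraction_x"] > pos["baseline_fraction_x"]


class TestFisherExact:
    def test_frozen_reference_values(self):
        # verified against exhaustive hypergeometric enumeration
        _, p = xd.fisher_exact([[1, 9], [11, 3]])
        assert p == pytest.approx(0.0027594561852200836, abs=1e-15)
        assert xd.fisher_exact([[5, 5], [5, 5]])[1] == 1.0
        assert xd.fisher_exact([[2, 0], [0, 2]])[1] == pytest.approx(1 / 3)

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            t = rng.integers(0, 15, (2, 2))
            if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
                continue
            _, p = xd.fisher_exact(t)
            assert p == pytest.approx(stats.fisher_exact(t)[1], rel=1e-9)

    def test_zero_margin_is_error(self):
        with pytest.raises(DataError, match="margin"):
            xd.fisher_exact([[0, 0], [1, 2]])

    def test_testis_enrichment_wiring(self, make_annotation):
        ann = make_annotation(
            {f"x{i}": "X" for i in range(10)} | {f"a{i}": "1" for i in range(40)}
        )
        max_tissue = pd.Series(
            ["testis"] * 8 + ["brain"] * 2 + ["testis"] * 4 + ["brain"] * 36,
            index=list(ann.gene_ids),
        )
        odds, p = xd.testis_enrichment(max_tissue, ann)
        assert odds > 1
        assert p < 0.001
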