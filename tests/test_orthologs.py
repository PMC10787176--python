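import numpy as np
import pandas as pd
import pytest

import xdosage as xd
from xdosage.io import DataError, OrthologMap
from xdosage.orthologs import CHICKEN_RULES, OPOSSUM_RULES, OutgroupRules

from conftest import build_annotation, build_matrix


def make_pairs(rows):
    return OrthologMap(
        pd.DataFrame(rows, columns=["focal_gene", "outgroup_gene",
                                    "focal_chrom", "outgroup_chrom"])
    )


class TestClassifyPairs:
    def test_chicken_rules(self):
        omap = make_pairs([
            ("fx1", "o1", "X", "4"),    # proto-X material -> X_pair
            ("fx2", "o2", "X", "7"),    # X ortholog off chr1/4 -> dropped
            ("fa1", "o3", "2", "3"),    # AA_pair
            ("fa2", "o4", "2", "Z"),    # outgroup sex chromosome -> dropped
        ])
        ann = build_annotation({"fx1": "X", "fx2": "X", "fa1": "2", "fa2": "2"})
        out = xd.classify_pairs(omap, ann, rules=CHICKEN_RULES)
        got = dict(zip(out["focal_gene"], out["pair_class"]))
        assert got == {"fx1": "X_pair", "fa1": "AA_pair"}

    def test_opossum_x_counts_as_autosome(self):
        omap = make_pairs([
            ("fx1", "o1", "X", "X"),
            ("fa1", "o2", "5", "X"),
        ])
        ann = build_annotation({"fx1": "X", "fa1": "5"})
        out = xd.classify_pairs(omap, ann, rules=OPOSSUM_RULES)
        got = dict(zip(out["focal_gene"], out["pair_class"]))
        assert got == {"fx1": "X_pair", "fa1": "AA_pair"}
        # without the rule the same pairs are dropped
        assert len(xd.classify_pairs(omap, ann, rules=OutgroupRules())) == 0


def paired_frame(rows):
    df = pd.DataFrame(rows, columns=["focal_gene", "outgroup_gene", "pair_class",
                                     "focal_value", "outgroup_value"])
    return df


class TestScaleBetweenSpecies:
    def test_constant_threefold_outgroup(self):
        rows = [(f"f{i}", f"o{i}", "AA_pair", v, 3 * v) for i, v in enumerate([2, 4, 8])]
        scaled, s = xd.scale_between_species(paired_frame(rows), cutoff=1.0)
        assert s == pytest.approx(1 / 3)
        assert np.allclose(scaled["outgroup_value"], scaled["focal_value"])

    def test_single_pair(self):
        scaled, s = xd.scale_between_species(
            paired_frame([("f", "o", "AA_pair", 4.0, 2.0)]), cutoff=1.0
        )
        assert s == 2.0

    def test_cutoff_applies_to_both_members(self):
        rows = [("f1", "o1", "AA_pair", 4.0, 0.5),  # outgroup below cutoff
                ("f2", "o2", "AA_pair", 0.5, 4.0),  # focal below cutoff
                ("f3", "o3", "AA_pair", 4.0, 4.0)]
        scaled, _ = xd.scale_between_species(paired_frame(rows), cutoff=1.0)
        assert list(scaled["focal_gene"]) == ["f3"]

    def test_no_retained_pairs_is_error(self):
        with pytest.raises(DataError, match="no ortholog pairs"):
            xd.scale_between_species(
                paired_frame([("f", "o", "AA_pair", 0.5, 0.5)]), cutoff=1.0
            )

    def test_scale_recovery_at_n1000(self):
        rng = np.random.default_rng(8)
        focal = rng.lognormal(2, 1, 1000)
        s_true = 3.0
        outgroup = focal / s_true * rng.lognormal(0, 0.1, 1000)
        rows = [(f"f{i}", f"o{i}", "AA_pair", f, o)
                for i, (f, o) in enumerate(zip(focal, outgroup))]
        _, s = xd.scale_between_species(paired_frame(rows), cutoff=0.0)
        assert s == pytest.approx(s_true, rel=0.02)


class TestXXXRatio:
    def test_identical_ratios_give_unity(self):
        rows = [("fx", "ox", "X_pair", 4.0, 2.0), ("fa", "oa", "AA_pair", 6.0, 3.0)]
        est = xd.xxx_ratio(paired_frame(rows))
        assert (est.x_xx, est.aa_aa) == (1.0, 1.0)

    def test_no_compensation_signature(self):
        # AA pairs at ratio 2 (median), X pairs at ratio 1 -> x_xx = 0.5
        rows = [("fa1", "oa1", "AA_pair", 4.0, 2.0),
                ("fa2", "oa2", "AA_pair", 8.0, 4.0),
                ("fx1", "ox1", "X_pair", 3.0, 3.0)]
        est = xd.xxx_ratio(paired_frame(rows))
        assert est.x_xx == 0.5
        assert est.aa_aa == 1.0

    def test_missing_class_is_error(self):
        with pytest.raises(DataError, match="pair classes"):
            xd.xxx_ratio(paired_frame([("fa", "oa", "AA_pair", 2.0, 2.0)]))

    def test_aa_median_exactly_one_even_pair_count(self):
        rng = np.random.default_rng(5)
        rows = [(f"f{i}", f"o{i}", "AA_pair", v, w)
                for i, (v, w) in enumerate(zip(rng.lognormal(1, 1, 50),
                                               rng.lognormal(1, 1, 50)))]
        rows += [("fx", "ox", "X_pair", 3.0, 2.0)]
        assert xd.xxx_ratio(paired_frame(rows)).aa_aa == 1.0


class TestPipelineProperties:
    @pytest.fixture()
    def dataset(self):
        params = xd.SimulationParams(
            n_autosomal_genes=400, n_x_genes=80, n_tissues=1, n_stages=2, seed=21
        )
        ann = xd.simulate_genome(params)
        matrix = xd.simulate_expression(ann, params)
        omap, og_matrix, og_ann = xd.simulate_outgroup(ann, params)
        return omap, matrix, og_matrix, og_ann

    def test_outgroup_scale_absorbed(self, dataset):
        omap, matrix, og_matrix, og_ann = dataset
        base = xd.xxx_pipeline(omap, matrix, og_matrix, cutoff=0.0,
                               outgroup_annotation=og_ann)
        scaled = xd.ExpressionMatrix(og_matrix.values * 7.25, og_matrix.annotation,
                                     og_matrix.samples)
        alt = xd.xxx_pipeline(omap, matrix, scaled, cutoff=0.0,
                              outgroup_annotation=og_ann)
        assert alt.x_xx == pytest.approx(base.x_xx, abs=1e-12)

    def test_invariant_to_pair_ordering(self, dataset):
        omap, matrix, og_matrix, og_ann = dataset
        base = xd.xxx_pipeline(omap, matrix, og_matrix, cutoff=1.0,
                               outgroup_annotation=og_ann)
        shuffled = OrthologMap(
            omap.pairs.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        alt = xd.xxx_pipeline(shuffled, matrix, og_matrix, cutoff=1.0,
                              outgroup_annotation=og_ann)
        assert alt.x_xx == base.x_xx
        assert (alt.n_x_pairs, alt.n_aa_pairs) == (base.n_x_pairs, base.n_aa_pairs)

    def test_final_ratio_insensitive_to_scaling_pool(self, dataset):
        # the AA:AA normalization cancels the species scale factor, so
        # scaling on AA pairs only gives the same x_xx as pooled scaling
        omap, matrix, og_matrix, og_ann = dataset
        classified = xd.classify_pairs(omap, matrix.annotation, og_ann)
        pairs = xd.paired_expression(classified, matrix, og_matrix)
        pooled, _ = xd.scale_between_species(pairs, cutoff=0.0)
        est_pooled = xd.xxx_ratio(pooled)
        aa_only = pairs[pairs["pair_class"] == "AA_pair"]
        s_aa = aa_only["focal_value"].median() / aa_only["outgroup_value"].median()
        alt = pairs.copy()
        alt["outgroup_value"] = alt["outgroup_value"] * s_aa
        est_alt = xd.xxx_ratio(alt)
        assert est_alt.x_xx == pytest.approx(est_pooled.x_xx, rel=1e-12)

    def test_zero_noise_recovers_compensation_exactly(self):
        params = xd.SimulationParams(
            n_autosomal_genes=100, n_x_genes=20, n_tissues=1, n_stages=2,
            compensation_factor=0.5, noise_log_sd=0.0,
            outgroup_noise_log_sd=0.0, species_scale=1.0, seed=2,
        )
        ann = xd.simulate_genome(params)
        matrix = xd.simulate_expression(ann, params)
        omap, og_matrix, og_ann = xd.simulate_outgroup(ann, params)
        est = xd.xxx_pipeline(omap, matrix, og_matrix, cutoff=0.0,
                              outgroup_annotation=og_ann)
        assert est.x_xx == pytest.approx(0.5, abs=1e-12)
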