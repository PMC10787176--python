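"""Cross-species X:XX and AA:AA expression ratios.

The ancestral proto-X is unobservable, so dosage compensation is tested
against an outgroup that diverged before the sex chromosomes arose: each
focal X-linked gene is compared with its 1:1 ortholog sitting on an outgroup
autosome (for chickens, chromosomes 1 and 4 carry the proto-X material).
Autosome-autosome ortholog pairs calibrate the comparison: expression is
median-scaled between species, the per-pair focal/outgroup ratios are
normalized so the AA:AA median is exactly 1, and X:XX is the median ratio
over X pairs -- 1 under full compensation, 0.5 with no compensation.

Pipeline order is fixed: filter (both members > cutoff) -> scale ->
normalize -> median.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix, GeneAnnotation, OrthologMap, SEX_CHROMOSOMES

import logging

logger = logging.getLogger("xdosage")


@dataclass(frozen=True)
class OutgroupRules:
    """Chromosome rules classifying ortholog pairs.

    ``allowed_x_chroms``: outgroup chromosomes an X-pair ortholog may sit on
    (empty = any outgroup autosome; for chickens this is {1, 4}).
    ``excluded_chroms``: outgroup chromosomes disqualifying an AA pair
    (typically the outgroup's own sex chromosomes, e.g. {Z, W}).
    ``x_as_autosome``: treat the outgroup's X chromosome as an ordinary
    autosome (the opossum rule: its X is the youngest stratum and is fully
    compensated, so it stands in for a pair of autosomes).
    """

    allowed_x_chroms: frozenset = frozenset()
    excluded_chroms: frozenset = frozenset({"Z", "W"})
    x_as_autosome: bool = False

    def outgroup_is_autosome(self, chrom: str) -> bool:
        if chrom in self.excluded_chroms:
            return False
        if chrom in SEX_CHROMOSOMES:
            return self.x_as_autosome and chrom == "X"
        return True


CHICKEN_RULES = OutgroupRules(allowed_x_chroms=frozenset({"1", "4"}))
OPOSSUM_RULES = OutgroupRules(excluded_chroms=frozenset({"Y"}), x_as_autosome=True)


@dataclass
class PairedExpression:
    """Expression of one ortholog pair in one context."""

    focal_gene: str
    outgroup_gene: str
    focal_value: float
    outgroup_value: float
    pair_class: str  # "X_pair" or "AA_pair"


def classify_pairs(
    orthologs: OrthologMap,
    focal_annotation: GeneAnnotation,
    outgroup_annotation: GeneAnnotation | None = None,
    rules: OutgroupRules = OutgroupRules(),
) -> pd.DataFrame:
    """Classify ortholog pairs into X_pairs and AA_pairs.

    X_pair: focal gene on X and outgroup ortholog on an allowed outgroup
    autosome.  AA_pair: focal gene autosomal and outgroup ortholog on an
    outgroup autosome not in the excluded set.  Pairs fitting neither class
    are dropped with a logged count.  Chromosomes are taken from the
    ortholog table itself (``outgroup_annotation`` may refine them when
    provided).
    """
    pairs = orthologs.pairs.copy()
    if outgroup_annotation is not None:
        known = pairs["outgroup_gene"].isin(outgroup_annotation.gene_ids)
        pairs.loc[known, "outgroup_chrom"] = outgroup_annotation.chromosome.loc[
            pairs.loc[known, "outgroup_gene"]
        ].to_numpy()
    focal_chrom = focal_annotation.chromosome
    known_focal = pairs["focal_gene"].isin(focal_annotation.gene_ids)
    pairs.loc[known_focal, "focal_chrom"] = focal_chrom.loc[
        pairs.loc[known_focal, "focal_gene"]
    ].to_numpy()

    focal_is_x = pairs["focal_chrom"] == "X"
    og_is_autosome = pairs["outgroup_chrom"].map(rules.outgroup_is_autosome)
    if rules.allowed_x_chroms:
        og_allowed_x = pairs["outgroup_chrom"].isin(rules.allowed_x_chroms)
    else:
        og_allowed_x = og_is_autosome
    focal_is_a = pairs["focal_chrom"].map(
        lambda c: c not in SEX_CHROMOSOMES and c not in {"MT", "M"}
    )
    is_x_pair = focal_is_x & og_allowed_x
    is_aa_pair = focal_is_a & og_is_autosome
    pairs["pair_class"] = np.select([is_x_pair, is_aa_pair], ["X_pair", "AA_pair"], default="")
    dropped = int((pairs["pair_class"] == "").sum())
    if dropped:
        logger.info("classify_pairs: dropped %d pairs fitting neither class", dropped)
    return pairs[pairs["pair_class"] != ""].reset_index(drop=True)


def paired_expression(
    classified: pd.DataFrame,
    focal_matrix: ExpressionMatrix,
    outgroup_matrix: ExpressionMatrix,
    tissue=None,
    stage_label=None,
) -> pd.DataFrame:
    """Attach per-context expression values (mean over selected samples)
    to classified pairs; pairs missing from either matrix are dropped."""
    fvals = focal_matrix.context_values(tissue=tissue, stage_label=stage_label)
    ovals = outgroup_matrix.context_values(tissue=tissue, stage_label=stage_label)
    out = classified.copy()
    out["focal_value"] = out["focal_gene"].map(fvals)
    out["outgroup_value"] = out["outgroup_gene"].map(ovals)
    return out.dropna(subset=["focal_value", "outgroup_value"]).reset_index(drop=True)


def scale_between_species(pairs: pd.DataFrame, cutoff: float = 1.0) -> tuple[pd.DataFrame, float]:
    """Median-scale outgroup expression onto the focal scale.

    Pairs with both members > cutoff are retained ("only the expressed genes
    need to be compensated"); outgroup values are multiplied by
    s = median(focal) / median(outgroup) over all retained pairs, X and AA
    pooled.  Returns (scaled pairs, s).
    """
    keep = (pairs["focal_value"] > cutoff) & (pairs["outgroup_value"] > cutoff)
    retained = pairs[keep].copy()
    if retained.empty:
        raise DataError(f"no ortholog pairs retained at cutoff {cutoff}")
    s = float(retained["focal_value"].median() / retained["outgroup_value"].median())
    retained["outgroup_value"] = retained["outgroup_value"] * s
    return retained.reset_index(drop=True), s


@dataclass
class XXXEstimate:
    x_xx: float
    aa_aa: float
    n_x_pairs: int
    n_aa_pairs: int
    scale_factor: float = float("nan")
    context: str = ""


def xxx_ratio(scaled_pairs: pd.DataFrame) -> XXXEstimate:
    """Median X:XX after normalizing the AA:AA ratio median to 1.

    Per-pair ratios focal/outgroup are divided by the AA-pair median so the
    AA:AA median is exactly 1 by construction; X:XX is the median normalized
    ratio over X pairs.
    """
    ratios = scaled_pairs["focal_value"] / scaled_pairs["outgroup_value"]
    is_x = scaled_pairs["pair_class"] == "X_pair"
    is_aa = scaled_pairs["pair_class"] == "AA_pair"
    if not is_x.any() or not is_aa.any():
        raise DataError(
            f"need both pair classes: {int(is_x.sum())} X_pairs, {int(is_aa.sum())} AA_pairs"
        )
    # medians are equivariant under positive scaling, so normalizing the
    # class medians (rather than every pair ratio) keeps AA:AA at exactly 1.0
    aa_median = float(ratios[is_aa].median())
    return XXXEstimate(
        x_xx=float(ratios[is_x].median()) / aa_median,
        aa_aa=aa_median / aa_median,
        n_x_pairs=int(is_x.sum()),
        n_aa_pairs=int(is_aa.sum()),
    )


def xxx_pipeline(
    orthologs: OrthologMap,
    focal_matrix: ExpressionMatrix,
    outgroup_matrix: ExpressionMatrix,
    rules: OutgroupRules = OutgroupRules(),
    cutoff: float = 1.0,
    tissue=None,
    stage_label=None,
    outgroup_annotation: GeneAnnotation | None = None,
) -> XXXEstimate:
    """classify -> pair values -> filter -> scale -> normalize -> median."""
    classified = classify_pairs(orthologs, focal_matrix.annotation, outgroup_annotation, rules)
    pairs = paired_expression(classified, focal_matrix, outgroup_matrix, tissue, stage_label)
    scaled, s = scale_between_species(pairs, cutoff)
    est = xxx_ratio(scaled)
    est.scale_factor = s
    est.context = str(tissue or "all samples")
    return est
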