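"""Tissue and developmental-stage specificity of gene expression (tau).

tau = sum_i(1 - a_i) / (n - 1) with a_i = x_i / max_i(x_i), over a gene's
expression profile across n tissues (or, within one tissue, across stages):
0 means broadly expressed, 1 means expressed in a single context.  A gene's
expression level in a tissue is its mean FPKM over all of that tissue's
developmental stages; genes at 0 in every tissue are excluded.  Because
tissues differ in how many stages were sampled, stage-specificity values are
not comparable across tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, ExpressionMatrix


def tau(profile) -> float:
    """Specificity index of one expression profile (n >= 2 contexts)."""
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise DataError("tau needs a 1-D profile over >= 2 contexts")
    if (x < 0).any():
        raise DataError("negative expression in profile")
    m = x.max()
    if m == 0:
        raise DataError("all-zero profile: gene must be excluded from tau")
    return float((1.0 - x / m).sum() / (len(x) - 1))


def tau_table(table: pd.DataFrame) -> pd.Series:
    """tau per gene for a gene x context table; all-zero genes are dropped."""
    x = table.to_numpy(dtype=float)
    m = x.max(axis=1)
    keep = m > 0
    vals = (1.0 - x[keep] / m[keep, None]).sum(axis=1) / (x.shape[1] - 1)
    return pd.Series(vals, index=table.index[keep], name="tau")


def tissue_mean_expression(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Gene x tissue table of mean expression over each tissue's samples."""
    tissues = sorted(matrix.samples["tissue"].unique())
    return pd.DataFrame(
        {t: matrix.context_values(tissue=t) for t in tissues}, index=matrix.gene_ids
    )


def stage_specificity(matrix: ExpressionMatrix, tissue: str) -> pd.Series:
    """Per-gene tau over developmental stages within one tissue.

    Stage expression is the mean over that stage's replicates.  All-zero
    genes are excluded; values are not comparable across tissues.
    """
    sub = matrix.samples[matrix.samples["tissue"] == tissue]
    if sub.empty:
        raise DataError(f"no samples for tissue {tissue!r}")
    stages = sorted(sub["stage_label"].unique())
    if len(stages) < 2:
        raise DataError(f"tissue {tissue!r} has fewer than 2 stages")
    table = pd.DataFrame(
        {s: matrix.context_values(tissue=tissue, stage_label=s) for s in stages}
    )
    return tau_table(table)


def max_tissue_assignment(table: pd.DataFrame) -> pd.DataFrame:
    """Assign each gene to its maximum-expression tissue.

    Ties are broken by the first tissue in sorted column order and flagged;
    all-zero genes are excluded.  Returns columns ``max_tissue``, ``tie``.
    """
    cols = sorted(table.columns)
    tbl = table[cols]
    x = tbl.to_numpy(dtype=float)
    keep = x.max(axis=1) > 0
    x = x[keep]
    arg = x.argmax(axis=1)  # first max in sorted order
    tie = (x == x.max(axis=1)[:, None]).sum(axis=1) > 1
    return pd.DataFrame(
        {"max_tissue": np.array(cols)[arg], "tie": tie}, index=tbl.index[keep]
    )


def tissue_specific_genes(
    table: pd.DataFrame,
    annotation=None,
    tau_threshold: float = 0.8,
) -> tuple[dict, pd.Series]:
    """Tissue-specific gene sets (tau > threshold, assigned to max tissue).

    Returns (per-tissue gene-id lists, per-tissue fraction of the specific
    genes that are X-linked -- NaN where ``annotation`` is not given).
    """
    taus = tau_table(table)
    assign = max_tissue_assignment(table)
    specific = taus.index[taus > tau_threshold]
    assign = assign.loc[assign.index.intersection(specific)]
    sets = {t: [] for t in sorted(table.columns)}
    for gene, row in assign.iterrows():
        sets[row["max_tissue"]].append(gene)
    fractions = {}
    for t, genes in sets.items():
        if annotation is None or not genes:
            fractions[t] = float("nan")
        else:
            chrom = annotation.chromosome.loc[genes]
            fractions[t] = float((chrom == "X").mean())
    return sets, pd.Series(fractions, name="fraction_x")


def ratio_vs_specific_fraction(ratios: dict, fractions: dict) -> tuple[float, float]:
    """Spearman correlation of per-tissue X:AA ratios with the per-tissue
    percentage of X-linked tissue-specific genes (>= 3 common tissues)."""
    common = sorted(set(ratios) & set(fractions))
    if len(common) < 3:
        raise DataError(f"need >= 3 common tissues, got {len(common)}")
    r = [ratios[t] for t in common]
    f = [fractions[t] for t in common]
    rho, p = stats.spearmanr(r, f)
    return float(rho), float(p)
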