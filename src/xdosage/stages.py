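"""Stage-correlated gene identification and chromosomal enrichment.

Within one tissue, each gene's expression is correlated (Spearman) with the
developmental-stage order of the samples, young to old; replicates within a
stage share a rank.  Genes with rho > 0.8 and P < 0.05 are
stage-positively-correlated, rho < -0.8 negatively.  The fraction of
X-linked genes among the classified sets, across a sweep of |rho|
thresholds, shows whether the X chromosome is enriched for rising or falling
expression trajectories; Fisher's exact test quantifies enrichment of a gene
class on a chromosome.

P-values: exact permutation enumeration for n <= 9 samples, the
t-approximation above that; no multiple-testing correction by default (a
Benjamini-Hochberg option exists).
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError, ExpressionMatrix, GeneAnnotation

EXACT_SPEARMAN_MAX_N = 9


def _spearman_rho(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    """Pearson correlation of midranks (handles ties exactly)."""
    xc = x_ranks - x_ranks.mean()
    yc = y_ranks - y_ranks.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float((xc @ yc) / denom)


@lru_cache(maxsize=256)
def _permutation_null(x_pattern: tuple, y_pattern: tuple) -> np.ndarray:
    """Sorted |rho| null distribution over all permutations of y.

    Depends only on the two rank multisets (permutation symmetry), so the
    cache is shared by every untied gene in a tissue.
    """
    x = np.asarray(x_pattern, dtype=float)
    perms = np.array(list(itertools.permutations(y_pattern)), dtype=float)
    xc = x - x.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc @ xc) * (pc * pc).sum(axis=1))
    with np.errstate(invalid="ignore"):
        rhos = (pc @ xc) / denom
    return np.sort(np.abs(rhos))


def spearman_exact_pvalue(x_ranks: np.ndarray, y_ranks: np.ndarray) -> float:
    """Two-sided permutation p for the Spearman rho of two rank vectors."""
    rho = _spearman_rho(np.asarray(x_ranks, float), np.asarray(y_ranks, float))
    if math.isnan(rho):
        return float("nan")
    null = _permutation_null(
        tuple(np.sort(np.asarray(x_ranks, float))),
        tuple(np.sort(np.asarray(y_ranks, float))),
    )
    # count |rho_perm| >= |rho_obs| with a float-noise guard
    k = np.searchsorted(null, abs(rho) - 1e-12, side="left")
    return float((len(null) - k) / len(null))


def _t_approx_pvalue(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return float(np.finfo(float).tiny)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(max(2.0 * stats.t.sf(abs(t), n - 2), np.finfo(float).tiny))


def stage_correlation(
    matrix: ExpressionMatrix,
    tissue: str,
    min_samples: int = 4,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of expression with stage rank.

    Returns a gene-indexed frame with ``rho``, ``p`` and ``n_samples``;
    genes with constant expression get NaN rho/p.  Exact permutation
    p-values for n <= 9 samples, t-approximation otherwise.
    """
    cols = matrix.select_samples(tissue=tissue)
    if len(cols) < min_samples:
        raise DataError(
            f"tissue {tissue!r}: {len(cols)} samples < required {min_samples}"
        )
    stage_ranks = matrix.samples.loc[cols, "stage_rank"].to_numpy(dtype=float)
    s_ranks = stats.rankdata(stage_ranks)
    expr = matrix.values[cols].to_numpy(dtype=float)
    n = len(cols)
    e_ranks = stats.rankdata(expr, axis=1)

    sc = s_ranks - s_ranks.mean()
    ec = e_ranks - e_ranks.mean(axis=1, keepdims=True)
    denom = np.sqrt((sc @ sc) * (ec * ec).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = np.where(denom > 0, (ec @ sc) / denom, np.nan)

    pvals = np.full(len(rhos), np.nan)
    if n <= EXACT_SPEARMAN_MAX_N:
        y_pattern = tuple(np.sort(s_ranks))
        for i, rho in enumerate(rhos):
            if math.isnan(rho):
                continue
            null = _permutation_null(tuple(np.sort(e_ranks[i])), y_pattern)
            k = np.searchsorted(null, abs(rho) - 1e-12, side="left")
            pvals[i] = (len(null) - k) / len(null)
    else:
        ok = ~np.isnan(rhos)
        pvals[ok] = [_t_approx_pvalue(r, n) for r in rhos[ok]]
    return pd.DataFrame(
        {"rho": rhos, "p": pvals, "n_samples": n}, index=matrix.gene_ids
    )


def classify_stage_correlated(
    results: pd.DataFrame,
    rho_threshold: float = 0.8,
    p_threshold: float = 0.05,
    adjust: bool = False,
) -> tuple[pd.Index, pd.Index]:
    """(positive, negative) stage-correlated gene sets; always disjoint.

    positive: rho > threshold and p < p_threshold; negative: rho <
    -threshold.  ``adjust=True`` applies Benjamini-Hochberg to the p-values
    first (off by default: raw per-gene p is the conventional screen).
    """
    p = results["p"]
    if adjust:
        p = pd.Series(
            stats.false_discovery_control(results["p"].fillna(1.0), method="bh"),
            index=results.index,
        )
    sig = p < p_threshold
    positive = results.index[(results["rho"] > rho_threshold) & sig]
    negative = results.index[(results["rho"] < -rho_threshold) & sig]
    return positive, negative


def xlinked_fraction_by_threshold(
    results: pd.DataFrame,
    annotation: GeneAnnotation,
    thresholds=(0.5, 0.6, 0.7, 0.8, 0.9),
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """X-linked fraction of stage-correlated genes across |rho| thresholds.

    One row per (threshold, sign); ``fraction_x`` is the share of classified
    genes on the X chromosome (NaN when the class is empty) and
    ``baseline_fraction_x`` the X share among all scored genes.
    """
    thresholds = list(thresholds)
    if sorted(thresholds) != thresholds:
        raise DataError("thresholds must be ascending")
    chrom = annotation.chromosome.reindex(results.index)
    baseline = float((chrom == "X").mean())
    rows = []
    for thr in thresholds:
        pos, neg = classify_stage_correlated(results, thr, p_threshold)
        for sign, genes in (("positive", pos), ("negative", neg)):
            frac = float((chrom.loc[genes] == "X").mean()) if len(genes) else float("nan")
            rows.append(
                {
                    "threshold": thr,
                    "sign": sign,
                    "n_classified": len(genes),
                    "fraction_x": frac,
                    "baseline_fraction_x": baseline,
                }
            )
    return pd.DataFrame(rows)


def fisher_exact(table) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The p-value sums hypergeometric probabilities no larger than the
    observed table's, computed with exact integer weights so probability
    ties are handled without float tolerance.  The odds ratio is the sample
    (a*d)/(b*c); a zero in b or c yields inf (Haldane correction is not
    applied, only noted).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise DataError("fisher_exact needs a 2x2 table of non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2 = a + b, c + d
    c1 = a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        raise DataError("fisher_exact: zero row or column margin")
    odds = (a * d) / (b * c) if b * c > 0 else float("inf")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    numer = sum(w for w in weights if w <= w_obs)
    p = numer / sum(weights)
    return float(odds), float(p)


def testis_enrichment(
    max_tissue: pd.Series, annotation: GeneAnnotation, tissue: str = "testis"
) -> tuple[float, float]:
    """Fisher's exact test: are X-linked genes enriched among genes whose
    maximum expression is in ``tissue``?"""
    chrom = annotation.chromosome.reindex(max_tissue.index)
    on_x = chrom == "X"
    in_t = max_tissue == tissue
    table = [
        [int((on_x & in_t).sum()), int((on_x & ~in_t).sum())],
        [int((~on_x & in_t).sum()), int((~on_x & ~in_t).sum())],
    ]
    return fisher_exact(table)
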