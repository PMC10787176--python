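"""Bin-matched X:AA comparison of protein abundances.

Mass-spectrometry coverage is shallow and noisy, so protein-level X:AA
comparisons are made between abundance-matched quantile bins rather than raw
means: X-linked and autosomal iBAQ values are separately sorted descending
and split into 100 near-equal bins, and only the 25 highest-abundance bins
from each class are compared (ratio of bin means, bin by bin).  A Wilcoxon
rank-sum test compares the two classes' values directly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataError

EXACT_RANKSUM_MAX_N = 10


@dataclass
class BinTable:
    """Quantile bins of one chromosome class, ordered by descending abundance."""

    chromosome_class: str
    bins: pd.DataFrame  # columns: bin_index (1-based), gene_id, value
    bin_means: pd.Series  # indexed by bin_index, non-increasing


def quantile_bins(abundances: pd.Series, n_bins: int = 100, chromosome_class: str = "") -> BinTable:
    """Split per-gene abundances into ``n_bins`` contiguous descending bins.

    Genes are sorted by descending abundance (ties broken by gene_id for
    determinism) and split into near-equal groups; when n is not divisible
    the first ``n % n_bins`` bins take one extra gene.  Errors when there
    are fewer genes than bins.
    """
    n = len(abundances)
    if n < n_bins:
        raise DataError(
            f"{n} genes < {n_bins} bins in class {chromosome_class!r}; use a smaller n_bins"
        )
    order = sorted(abundances.items(), key=lambda kv: (-kv[1], kv[0]))
    base, rem = divmod(n, n_bins)
    rows = []
    cursor = 0
    for b in range(1, n_bins + 1):
        size = base + (1 if b <= rem else 0)
        for gene_id, value in order[cursor : cursor + size]:
            rows.append({"bin_index": b, "gene_id": gene_id, "value": float(value)})
        cursor += size
    df = pd.DataFrame(rows)
    means = df.groupby("bin_index")["value"].mean()
    return BinTable(chromosome_class, df, means)


def bin_matched_ratio(
    x_bins: BinTable, a_bins: BinTable, top_k: int = 25, summary: str = "median"
) -> tuple[pd.Series, float]:
    """Per-bin X:AA ratios over the ``top_k`` highest-abundance bins.

    ratio_i = X bin-i mean / autosome bin-i mean; a zero autosomal bin mean
    yields NaN for that bin.  Returns (per-bin ratios, summary over bins)
    where ``summary`` is the median (default) or mean of the k ratios.
    """
    for tbl in (x_bins, a_bins):
        if len(tbl.bin_means) < top_k:
            raise DataError(f"need >= {top_k} bins, got {len(tbl.bin_means)}")
    idx = range(1, top_k + 1)
    x = x_bins.bin_means.loc[idx]
    a = a_bins.bin_means.loc[idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = pd.Series(np.where(a > 0, x / a, np.nan), index=pd.Index(idx, name="bin_index"))
    if summary == "median":
        s = float(ratios.median())
    elif summary == "mean":
        s = float(ratios.mean())
    else:
        raise DataError(f"unknown summary {summary!r}")
    return ratios, s


def _exact_ranksum_pvalue(x: np.ndarray, a: np.ndarray) -> float:
    """Two-sided p by full enumeration of group labelings on the midranks."""
    pooled = np.concatenate([x, a])
    ranks = stats.rankdata(pooled)
    n1, n = len(x), len(pooled)
    mean_w = n1 * (n + 1) / 2.0
    w_obs = ranks[:n1].sum()
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(n), n1):
        w = ranks[list(combo)].sum()
        total += 1
        if abs(w - mean_w) >= dev_obs - 1e-9:
            count += 1
    return count / total


def ranksum_compare(x_values, a_values) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of two classes.

    Exact enumeration of labelings when both samples have <= 10 values
    (tie-aware, via midranks); otherwise the normal approximation with tie
    correction.  Returns (U statistic for the first sample, p).
    """
    x = np.asarray(list(x_values), dtype=float)
    a = np.asarray(list(a_values), dtype=float)
    if len(x) == 0 or len(a) == 0:
        raise DataError("both samples must be non-empty")
    # U statistic from midranks (degenerate all-tied inputs stay well-defined)
    ranks = stats.rankdata(np.concatenate([x, a]))
    u = float(ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0)
    if len(x) <= EXACT_RANKSUM_MAX_N and len(a) <= EXACT_RANKSUM_MAX_N:
        return u, float(_exact_ranksum_pvalue(x, a))
    res = stats.mannwhitneyu(x, a, alternative="two-sided", method="asymptotic")
    return u, float(res.pvalue)
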