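"""X:AA expression ratios with size-matched bootstrap confidence intervals.

The point estimator is the ratio of means (mean expression of X-linked genes
over mean expression of autosomal genes), computed within one context (a
tissue, a tissue+stage, or an explicit sample set) after an expression
filter (conventionally FPKM > 1; a ratio near 1 is the full-compensation
signature).  Uncertainty is assessed by resampling, 1000 times, a set of
autosomal genes size-matched to the filtered X set (without replacement, the
X set held fixed) and taking empirical percentiles of the replicate ratios
as a 90% interval: the error bar describes the sampling variability of the
autosomal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix, expressed_mask

ALL_GENES = "all"  # cutoff sentinel: apply no expression filter


@dataclass
class RatioEstimate:
    """A point X:AA ratio with optional bootstrap CI and bookkeeping."""

    ratio: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_x: int = 0
    n_a: int = 0
    cutoff: float | str = 1.0
    context: str = ""

    def __post_init__(self):
        if not (math.isnan(self.ci_low) or self.ci_low <= self.ci_high):
            raise ValueError("ci_low must not exceed ci_high")


def _context_label(tissue, stage_label, sample_ids) -> str:
    parts = [p for p in (tissue, stage_label) if p is not None]
    if sample_ids is not None:
        parts.append(f"{len(list(sample_ids))} samples")
    return "/".join(map(str, parts)) or "all samples"


def _filtered_class_values(
    matrix: ExpressionMatrix,
    cutoff,
    tissue=None,
    stage_label=None,
    sample_ids=None,
):
    """Per-gene context means of X and autosomal genes surviving the filter."""
    values = matrix.context_values(tissue, stage_label, sample_ids)
    if cutoff == ALL_GENES or cutoff is None:
        keep = pd.Series(True, index=values.index)
    else:
        keep = expressed_mask(values, float(cutoff), strict=True)
    x_vals = values[keep & matrix.is_x()]
    a_vals = values[keep & matrix.is_autosomal()]
    return x_vals, a_vals


def xaa_ratio(
    matrix: ExpressionMatrix,
    cutoff: float | str = 1.0,
    tissue=None,
    stage_label=None,
    sample_ids=None,
) -> RatioEstimate:
    """Point X:AA ratio: mean(filtered X) / mean(filtered autosomes).

    Filtering at ``cutoff`` is strict (value > cutoff), applied to the
    context means; ``cutoff=ALL_GENES`` disables the filter.  Errors if no
    X or no autosomal gene survives.
    """
    label = _context_label(tissue, stage_label, sample_ids)
    x_vals, a_vals = _filtered_class_values(matrix, cutoff, tissue, stage_label, sample_ids)
    if len(x_vals) == 0 or len(a_vals) == 0:
        raise DataError(
            f"context {label!r}, cutoff {cutoff}: "
            f"{len(x_vals)} X and {len(a_vals)} autosomal genes survive the filter"
        )
    return RatioEstimate(
        ratio=float(x_vals.mean() / a_vals.mean()),
        n_x=len(x_vals),
        n_a=len(a_vals),
        cutoff=cutoff,
        context=label,
    )


def _nearest_rank(sorted_values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: the ceil(p*n)-th smallest value (1-based)."""
    n = len(sorted_values)
    k = min(max(int(math.ceil(p * n)), 1), n)
    return float(sorted_values[k - 1])


def bootstrap_replicates(
    x_values: np.ndarray,
    a_values: np.ndarray,
    n_boot: int,
    seed: int,
    with_replacement: bool = False,
) -> np.ndarray:
    """Replicate ratios mean(X)/mean(sampled A), size-matched to the X set."""
    x_values = np.asarray(x_values, dtype=float)
    a_values = np.asarray(a_values, dtype=float)
    n_x, n_a = len(x_values), len(a_values)
    if not with_replacement and n_a < n_x:
        raise DataError(f"cannot sample {n_x} autosomal genes from {n_a} without replacement")
    rng = np.random.default_rng(seed)
    x_mean = x_values.mean()
    if with_replacement:
        idx = rng.integers(0, n_a, size=(n_boot, n_x))
    else:
        keys = rng.random((n_boot, n_a))
        idx = np.argpartition(keys, n_x - 1, axis=1)[:, :n_x]
    return x_mean / a_values[idx].mean(axis=1)


def bootstrap_xaa(
    matrix: ExpressionMatrix,
    cutoff: float | str = 1.0,
    tissue=None,
    stage_label=None,
    sample_ids=None,
    n_boot: int = 1000,
    level: float = 0.90,
    seed: int = 0,
    with_replacement: bool = False,
) -> RatioEstimate:
    """X:AA ratio with a size-matched bootstrap confidence interval.

    Each replicate draws, without replacement, as many autosomal genes as
    there are filtered X genes and recomputes the ratio against the fixed X
    set; the CI bounds are nearest-rank percentiles of the replicates at
    (1-level)/2 and 1-(1-level)/2.
    """
    est = xaa_ratio(matrix, cutoff, tissue, stage_label, sample_ids)
    x_vals, a_vals = _filtered_class_values(matrix, cutoff, tissue, stage_label, sample_ids)
    reps = np.sort(
        bootstrap_replicates(
            x_vals.to_numpy(), a_vals.to_numpy(), n_boot, seed, with_replacement
        )
    )
    alpha = (1.0 - level) / 2.0
    est.ci_low = _nearest_rank(reps, alpha)
    est.ci_high = _nearest_rank(reps, 1.0 - alpha)
    return est


def ratio_cutoff_series(
    matrix: ExpressionMatrix,
    cutoffs,
    tissue=None,
    stage_label=None,
    sample_ids=None,
    include_all_genes: bool = True,
) -> list[RatioEstimate | None]:
    """One X:AA estimate per expression cutoff, plus an unfiltered entry.

    The cutoff-0 entry retains genes with value > 0 (the "zero" cutoff);
    the all-genes sentinel applies no filter at all, so the two differ
    exactly when some gene has value 0.  A cutoff at which one gene class
    empties is recorded as None.
    """
    cutoffs = list(cutoffs)
    if sorted(cutoffs) != cutoffs:
        raise DataError("cutoffs must be sorted ascending")
    series: list[RatioEstimate | None] = []
    all_cutoffs = ([ALL_GENES] if include_all_genes else []) + cutoffs
    for cutoff in all_cutoffs:
        try:
            series.append(xaa_ratio(matrix, cutoff, tissue, stage_label, sample_ids))
        except DataError:
            series.append(None)
    return series


def hkg_ratios(
    matrix: ExpressionMatrix,
    ahkg_ids,
    xhkg_ids,
    cutoff: float | str = 1.0,
    tissue=None,
    stage_label=None,
    sample_ids=None,
) -> tuple[float, float]:
    """(X:AHKG, XHKG:AHKG) ratios against housekeeping-gene references.

    Housekeeping genes are stably expressed, so X:AHKG tracks the expression
    trajectory of X-linked genes while XHKG:AHKG stays flat unless the X
    housekeeping complement itself changes.
    """
    values = matrix.context_values(tissue, stage_label, sample_ids)
    if cutoff == ALL_GENES or cutoff is None:
        keep = pd.Series(True, index=values.index)
    else:
        keep = expressed_mask(values, float(cutoff), strict=True)
    x_vals = values[keep & matrix.is_x()]
    ahkg = values[keep & values.index.isin(set(ahkg_ids))]
    xhkg = values[keep & values.index.isin(set(xhkg_ids))]
    for name, vals in (("AHKG", ahkg), ("XHKG", xhkg), ("X", x_vals)):
        if len(vals) == 0:
            raise DataError(f"{name} gene set empty after filtering at cutoff {cutoff}")
    return float(x_vals.mean() / ahkg.mean()), float(xhkg.mean() / ahkg.mean())


def unexpressed_fraction(
    matrix: ExpressionMatrix,
    cutoff: float = 1.0,
    tissue=None,
    stage_label=None,
    sample_ids=None,
) -> pd.DataFrame:
    """Fraction of unexpressed genes (value <= cutoff) on X vs autosomes.

    Returns one row per chromosome class plus the X-over-autosome fold
    (NaN when the autosomal fraction is zero).
    """
    values = matrix.context_values(tissue, stage_label, sample_ids)
    rows = []
    for cls, mask in (("X", matrix.is_x()), ("autosomes", matrix.is_autosomal())):
        sub = values[mask]
        if len(sub) == 0:
            raise DataError(f"no genes in class {cls}")
        rows.append({"chromosome_class": cls, "fraction": float((sub <= cutoff).mean())})
    frac_x, frac_a = rows[0]["fraction"], rows[1]["fraction"]
    fold = frac_x / frac_a if frac_a > 0 else float("nan")
    out = pd.DataFrame(rows)
    out["fold_x_over_a"] = fold
    return out


def combine_ratio_sources(ratios_by_source: dict) -> dict:
    """Per-tissue arithmetic mean of ratios from multiple data sources.

    When a tissue is covered by several datasets, its X:AA ratio is the mean
    of the per-source ratios; a tissue with an empty list is an error.
    """
    combined = {}
    for tissue, ratios in ratios_by_source.items():
        ratios = list(ratios)
        if not ratios:
            raise DataError(f"tissue {tissue!r} has no source ratios")
        combined[tissue] = float(np.mean(ratios))
    return combined
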