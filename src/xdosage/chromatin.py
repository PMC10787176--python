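"""Promoter chromatin-state diversity across epigenomes.

Promoters are the 2 kb upstream / 1 kb downstream window around each TSS
(strand-aware).  Intersecting every promoter with each epigenome's 15-state
chromHMM segmentation -- any overlap of at least 1 bp annotates the promoter
with that state -- yields per-gene state sets; the number of distinct states
a gene displays across all epigenomes measures how variable its regulation
is, and the per-chromosome base composition of states shows, e.g., the
excess of quiescent promoter sequence on the X chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ChromatinSegmentation, DataError, GeneAnnotation
from .proteome import ranksum_compare


def promoter_intervals(
    annotation: GeneAnnotation, upstream: int = 2000, downstream: int = 1000
) -> pd.DataFrame:
    """Strand-aware promoter windows, 0-based half-open, clipped at 0.

    + strand, TSS t: [t - upstream, t + downstream).  - strand genes are
    reflected so "upstream" follows transcription: [t - downstream + 1,
    t + upstream + 1).  The TSS base itself belongs to the downstream side
    on both strands.
    """
    tbl = annotation.table
    tss = tbl["tss"].to_numpy(dtype=np.int64)
    plus = (tbl["strand"] == "+").to_numpy()
    start = np.where(plus, tss - upstream, tss - downstream + 1)
    end = np.where(plus, tss + downstream, tss + upstream + 1)
    start = np.maximum(start, 0)
    return pd.DataFrame(
        {
            "chromosome": tbl["chromosome"].to_numpy(),
            "start": start,
            "end": end,
        },
        index=tbl.index,
    )


@dataclass
class GeneStateProfile:
    """Distinct states and per-state base counts for one gene, accumulated
    over epigenomes."""

    gene_id: str
    states: set = field(default_factory=set)
    per_state_bases: dict = field(default_factory=dict)

    @property
    def total_states(self) -> int:
        return len(self.states)


def intersect_states(
    promoters: pd.DataFrame,
    segmentation: ChromatinSegmentation,
    min_overlap: int = 1,
) -> dict[str, dict[str, int]]:
    """Per-gene state -> overlapped-base-count for one epigenome.

    A state annotates a gene iff its segments overlap the promoter by at
    least ``min_overlap`` bases (summed per state).  The segmentation's
    intervals are disjoint per chromosome, so binary search over the sorted
    segments finds all overlaps exactly.
    """
    result: dict[str, dict[str, int]] = {}
    seg_by_chrom = {
        chrom: sub.sort_values("start")
        for chrom, sub in segmentation.intervals.groupby("chrom", sort=False)
    }
    for chrom, prom_sub in promoters.groupby("chromosome", sort=False):
        sub = seg_by_chrom.get(chrom)
        if sub is None:
            sub = seg_by_chrom.get("chr" + str(chrom))
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        states = sub["state"].to_numpy()
        for gene_id, p_start, p_end in zip(
            prom_sub.index, prom_sub["start"].to_numpy(), prom_sub["end"].to_numpy()
        ):
            i0 = np.searchsorted(ends, p_start, side="right")
            i1 = np.searchsorted(starts, p_end, side="left")
            if i1 <= i0:
                continue
            overlaps = np.minimum(ends[i0:i1], p_end) - np.maximum(starts[i0:i1], p_start)
            per_state: dict[str, int] = {}
            for state, ov in zip(states[i0:i1], overlaps):
                if ov > 0:
                    per_state[state] = per_state.get(state, 0) + int(ov)
            per_state = {s: b for s, b in per_state.items() if b >= min_overlap}
            if per_state:
                result[gene_id] = per_state
    return result


def accumulate_profiles(
    per_epigenome: list[dict[str, dict[str, int]]]
) -> dict[str, GeneStateProfile]:
    """Union state sets and sum base counts over epigenomes."""
    profiles: dict[str, GeneStateProfile] = {}
    for epi in per_epigenome:
        for gene_id, per_state in epi.items():
            prof = profiles.setdefault(gene_id, GeneStateProfile(gene_id))
            for state, bases in per_state.items():
                prof.states.add(state)
                prof.per_state_bases[state] = prof.per_state_bases.get(state, 0) + bases
    return profiles


def state_diversity(
    profiles: dict[str, GeneStateProfile], annotation: GeneAnnotation
) -> dict:
    """Median distinct-state counts, X vs autosomes, with a rank-sum p.

    A gene's count is the number of distinct states over the union of all
    epigenomes' annotations of its promoter.
    """
    counts = pd.Series({g: p.total_states for g, p in profiles.items()})
    chrom = annotation.chromosome.reindex(counts.index)
    x_counts = counts[chrom == "X"]
    is_auto = annotation.is_autosomal().reindex(counts.index).fillna(False)
    a_counts = counts[is_auto.to_numpy()]
    if len(x_counts) == 0 or len(a_counts) == 0:
        raise DataError("state_diversity needs genes in both chromosome classes")
    _, p = ranksum_compare(x_counts.to_numpy(), a_counts.to_numpy())
    return {
        "median_x": float(x_counts.median()),
        "median_autosomes": float(a_counts.median()),
        "n_x": int(len(x_counts)),
        "n_autosomes": int(len(a_counts)),
        "p": float(p),
        "counts": counts,
    }


def state_base_fraction(
    profiles: dict[str, GeneStateProfile], annotation: GeneAnnotation
) -> pd.DataFrame:
    """Per-chromosome fraction of annotated promoter bases in each state.

    Base counts are summed over genes and epigenomes; fractions within one
    chromosome sum to 1.  Chromosomes with zero annotated bases are omitted.
    """
    records: dict[str, dict[str, int]] = {}
    chrom_of = annotation.chromosome
    for gene_id, prof in profiles.items():
        chrom = chrom_of.get(gene_id)
        if chrom is None:
            continue
        bucket = records.setdefault(chrom, {})
        for state, bases in prof.per_state_bases.items():
            bucket[state] = bucket.get(state, 0) + bases
    rows = []
    for chrom, by_state in records.items():
        total = sum(by_state.values())
        if total == 0:
            continue
        for state, bases in by_state.items():
            rows.append(
                {
                    "chromosome": chrom,
                    "state": state,
                    "bases": bases,
                    "fraction": bases / total,
                }
            )
    return pd.DataFrame(rows)


def promoter_state_analysis(
    annotation: GeneAnnotation,
    segmentations: list[ChromatinSegmentation],
    upstream: int = 2000,
    downstream: int = 1000,
    min_overlap: int = 1,
) -> dict:
    """End-to-end promoter/state pipeline over a set of epigenomes."""
    if not segmentations:
        raise DataError("need at least one epigenome segmentation")
    promoters = promoter_intervals(annotation, upstream, downstream)
    per_epi = [intersect_states(promoters, seg, min_overlap) for seg in segmentations]
    profiles = accumulate_profiles(per_epi)
    return {
        "profiles": profiles,
        "diversity": state_diversity(profiles, annotation),
        "base_fractions": state_base_fraction(profiles, annotation),
    }
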