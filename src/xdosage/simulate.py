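"""Synthetic developmental-transcriptome generator with known ground truth.

The generator emulates the statistical structure that X:AA / X:XX analyses
assume: log-normal FPKM-scale expression, a multiplicative compensation
factor on X-linked genes, tissue-specific genes (strongly expressed in one
home tissue, near-silent elsewhere), monotone stage-trending genes,
chromosome-specific excesses of unexpressed genes, an outgroup species whose
orthologs of focal X genes sit on autosomes at the ancestral
(pre-compensation) expression level, a noisy proteome derived from mRNA, and
chromHMM-style promoter segmentations whose per-gene state palettes differ
between X and autosomes.

Every generator is fully deterministic under ``SimulationParams.seed``; each
operation derives its own stream from the seed plus a fixed tag, so the
outputs do not depend on call order.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ChromatinSegmentation,
    ExpressionMatrix,
    GeneAnnotation,
    OrthologMap,
)

CANONICAL_TISSUES = ["brain", "cerebellum", "heart", "kidney", "liver", "ovary", "testis"]

#: the Roadmap 15-state chromHMM vocabulary
CHROMHMM_STATES = [
    "1_TssA", "2_TssAFlnk", "3_TxFlnk", "4_Tx", "5_TxWk", "6_EnhG", "7_Enh",
    "8_ZNF/Rpts", "9_Het", "10_TssBiv", "11_BivFlnk", "12_EnhBiv",
    "13_ReprPC", "14_ReprPCWk", "15_Quies",
]
QUIESCENT = "15_Quies"

_GENE_SLOT = 10_000  # bp between consecutive TSS slots; keeps promoters disjoint
_SLOT_JITTER = 4_000
_SLOT_OFFSET = 5_000


@dataclass(frozen=True)
class SimulationParams:
    """Ground-truth parameters of one synthetic dataset.

    ``compensation_factor`` multiplies every X-linked expression value
    relative to the gene's own ancestral level, so X:AA and X:XX share one
    ground truth; X:AA dynamics can then only arise from gene content
    (tissue-specific / stage-trending / unexpressed fractions).
    """

    n_autosomal_genes: int = 2000
    n_x_genes: int = 200
    n_tissues: int = 5
    n_stages: int = 8
    n_replicates: int = 1
    compensation_factor: float = 1.0
    frac_tissue_specific_x: float = 0.0
    frac_tissue_specific_a: float = 0.0
    frac_stage_pos_x: float = 0.0
    frac_stage_neg_x: float = 0.0
    frac_stage_pos_a: float = 0.0
    frac_stage_neg_a: float = 0.0
    frac_unexpressed_x: float = 0.0
    frac_unexpressed_a: float = 0.0
    log_sd: float = 1.0
    base_log_mean: float = math.log(10.0)  # median expressed gene ~10 FPKM
    noise_log_sd: float = 0.25
    specific_boost: float = 10.0
    off_tissue_level: float = 0.01
    x_tissue_preference: float = 0.75
    trend_log_range: float = 2.0
    species_scale: float = 3.0
    outgroup_noise_log_sd: float = 0.25
    proteome_exponent: float = 1.0
    proteome_log_sd: float = 0.25
    palette_size_x: int = 12
    palette_size_a: int = 9
    states_per_promoter: int = 3
    promoter_quies_frac_x: float = 0.0
    promoter_quies_frac_a: float = 0.0
    seed: int = 0

    def __post_init__(self):
        fracs = {
            "frac_tissue_specific_x": self.frac_tissue_specific_x,
            "frac_tissue_specific_a": self.frac_tissue_specific_a,
            "frac_stage_pos_x": self.frac_stage_pos_x,
            "frac_stage_neg_x": self.frac_stage_neg_x,
            "frac_stage_pos_a": self.frac_stage_pos_a,
            "frac_stage_neg_a": self.frac_stage_neg_a,
            "frac_unexpressed_x": self.frac_unexpressed_x,
            "frac_unexpressed_a": self.frac_unexpressed_a,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for cls in ("x", "a"):
            total = (
                fracs[f"frac_tissue_specific_{cls}"]
                + fracs[f"frac_stage_pos_{cls}"]
                + fracs[f"frac_stage_neg_{cls}"]
                + fracs[f"frac_unexpressed_{cls}"]
            )
            if total > 1.0 + 1e-12:
                raise ValueError(f"{cls.upper()} role fractions sum to {total} > 1")
        if self.n_autosomal_genes < 0 or self.n_x_genes < 0:
            raise ValueError("gene counts must be non-negative")
        if self.log_sd <= 0 or self.proteome_log_sd < 0:
            raise ValueError("dispersions must be positive")
        if not 1 <= max(self.palette_size_x, self.palette_size_a) <= 14:
            raise ValueError("palette sizes must be in 1..14 (15_Quies is reserved)")

    @property
    def tissues(self) -> list[str]:
        base = CANONICAL_TISSUES
        if self.n_tissues <= len(base):
            return base[: self.n_tissues]
        return base + [f"tissue{i}" for i in range(len(base), self.n_tissues)]

    @property
    def preferred_x_tissue(self) -> str:
        tissues = self.tissues
        return "testis" if "testis" in tissues else tissues[-1]


def structural_divergence_params(seed: int = 0, **overrides) -> SimulationParams:
    """The gene-content divergence scenario: full compensation (c = 1) but
    X-enriched tissue-specific and stage-trending genes plus an excess of
    unexpressed X genes.

    Fractions follow the magnitudes reported for mammalian X chromosomes:
    ~34% of X-linked genes tissue-specific with a testis preference, and
    unexpressed fractions of 0.34 (X) vs 0.20 (autosomes), i.e. a ~1.7-fold
    excess of silent genes on X at the FPKM = 0 cutoff.
    """
    base = dict(
        n_tissues=7,
        compensation_factor=1.0,
        frac_tissue_specific_x=0.34,
        frac_tissue_specific_a=0.10,
        frac_stage_pos_x=0.10,
        frac_stage_neg_x=0.05,
        frac_stage_pos_a=0.05,
        frac_stage_neg_a=0.05,
        frac_unexpressed_x=0.34,
        frac_unexpressed_a=0.20,
        seed=seed,
    )
    base.update(overrides)
    return SimulationParams(**base)


def _rng(params: SimulationParams, tag: str) -> np.random.Generator:
    # crc32 gives a process-independent tag hash (unlike builtin hash())
    return np.random.default_rng(
        np.random.SeedSequence((params.seed, zlib.crc32(tag.encode())))
    )


# ---------------------------------------------------------------------------
# genome


def simulate_genome(params: SimulationParams) -> GeneAnnotation:
    """Assign genes to chromosomes 1..22 (round-robin) and X.

    TSS positions are laid out in per-gene slots (fixed spacing, uniform
    jitter within the slot) so that promoter intervals of neighbouring genes
    never overlap -- a requirement for emitting valid chromHMM-style
    segmentations.
    """
    rng = _rng(params, "genome")
    n_a, n_x = params.n_autosomal_genes, params.n_x_genes
    gene_ids = [f"a{i:05d}" for i in range(n_a)] + [f"x{i:05d}" for i in range(n_x)]
    chroms = [str(1 + (i % 22)) for i in range(n_a)] + ["X"] * n_x
    slot_index: dict[str, int] = {}
    tss = np.empty(len(gene_ids), dtype=np.int64)
    for i, chrom in enumerate(chroms):
        j = slot_index.get(chrom, 0)
        slot_index[chrom] = j + 1
        tss[i] = _SLOT_OFFSET + j * _GENE_SLOT + rng.integers(0, _SLOT_JITTER)
    strand = np.where(rng.random(len(gene_ids)) < 0.5, "+", "-")
    table = pd.DataFrame(
        {
            "chromosome": chroms,
            "biotype": "protein_coding",
            "tss": tss,
            "strand": strand,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneAnnotation(table)


# ---------------------------------------------------------------------------
# expression


def _sample_sheet(params: SimulationParams, species: str, prefix: str = "") -> pd.DataFrame:
    rows = []
    for tissue in params.tissues:
        for s in range(1, params.n_stages + 1):
            for r in range(1, params.n_replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{prefix}{tissue}_s{s:02d}_r{r}",
                        "species": species,
                        "tissue": tissue,
                        "stage_label": f"s{s:02d}",
                        "stage_rank": s,
                        "sex": "unknown",
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def simulated_gene_roles(annotation: GeneAnnotation, params: SimulationParams) -> pd.DataFrame:
    """Ground-truth role assignment: columns ``role`` (baseline /
    tissue_specific / stage_pos / stage_neg / unexpressed) and
    ``home_tissue`` (tissue-specific genes only, else '')."""
    rng = _rng(params, "roles")
    roles = pd.Series("baseline", index=annotation.gene_ids, name="role")
    home = pd.Series("", index=annotation.gene_ids, name="home_tissue")
    tissues = params.tissues
    preferred = params.preferred_x_tissue
    for is_x in (True, False):
        cls = "x" if is_x else "a"
        ids = annotation.x_genes if is_x else annotation.autosomal_genes
        ids = np.array(ids)
        rng.shuffle(ids)
        n = len(ids)
        n_spec = round(getattr(params, f"frac_tissue_specific_{cls}") * n)
        n_pos = round(getattr(params, f"frac_stage_pos_{cls}") * n)
        n_neg = round(getattr(params, f"frac_stage_neg_{cls}") * n)
        n_un = round(getattr(params, f"frac_unexpressed_{cls}") * n)
        cursor = 0
        spec_ids = ids[cursor : cursor + n_spec]
        cursor += n_spec
        roles[spec_ids] = "tissue_specific"
        if is_x:
            pref = rng.random(len(spec_ids)) < params.x_tissue_preference
            home[spec_ids[pref]] = preferred
            others = spec_ids[~pref]
            home[others] = rng.choice(tissues, size=len(others))
        else:
            home[spec_ids] = rng.choice(tissues, size=len(spec_ids))
        for role, count in (("stage_pos", n_pos), ("stage_neg", n_neg), ("unexpressed", n_un)):
            roles[ids[cursor : cursor + count]] = role
            cursor += count
    return pd.DataFrame({"role": roles, "home_tissue": home})


def _deterministic_levels(
    annotation: GeneAnnotation, params: SimulationParams, ancestral: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Noise-free expression levels (genes x samples) and the role table.

    With ``ancestral=True`` the compensation factor is not applied and the
    lineage-specific silencing of 'unexpressed' genes is undone: that is the
    proto-X expression state an outgroup ortholog inherits.
    """
    rng = _rng(params, "base")
    base = np.exp(params.base_log_mean + params.log_sd * rng.standard_normal(len(annotation)))
    base = pd.Series(base, index=annotation.gene_ids)
    roles = simulated_gene_roles(annotation, params)
    samples = _sample_sheet(params, species="focal")
    n_st = params.n_stages
    stage_pos = np.exp(
        params.trend_log_range
        * ((np.arange(1, n_st + 1) - 1) / max(n_st - 1, 1) - 0.5)
    )
    levels = pd.DataFrame(0.0, index=annotation.gene_ids, columns=samples.index)
    role = roles["role"]
    for sample_id, meta in samples.iterrows():
        col = base.copy()
        spec = role == "tissue_specific"
        at_home = spec & (roles["home_tissue"] == meta["tissue"])
        col[at_home] *= params.specific_boost
        col[spec & ~at_home] *= params.off_tissue_level
        s_idx = int(meta["stage_rank"]) - 1
        col[role == "stage_pos"] *= stage_pos[s_idx]
        col[role == "stage_neg"] *= stage_pos[n_st - 1 - s_idx]
        if not ancestral:
            col[role == "unexpressed"] = 0.0
        levels[sample_id] = col
    if not ancestral:
        levels.loc[annotation.is_x().to_numpy(), :] *= params.compensation_factor
    return levels, roles


def simulate_expression(annotation: GeneAnnotation, params: SimulationParams) -> ExpressionMatrix:
    """Draw the focal species' FPKM matrix.

    Per-gene baselines are log-normal(``base_log_mean``, ``log_sd``); every
    X-linked value is multiplied by ``compensation_factor``; tissue-specific,
    stage-trending and unexpressed roles modulate the deterministic level;
    multiplicative log-normal sample noise (``noise_log_sd``) is applied last.
    """
    levels, _ = _deterministic_levels(annotation, params)
    rng = _rng(params, "expression-noise")
    noise = np.exp(params.noise_log_sd * rng.standard_normal(levels.shape))
    values = levels * noise
    return ExpressionMatrix(values, annotation, _sample_sheet(params, species="focal"))


# ---------------------------------------------------------------------------
# outgroup / orthologs


def simulate_outgroup(
    annotation: GeneAnnotation, params: SimulationParams
) -> tuple[OrthologMap, ExpressionMatrix, GeneAnnotation]:
    """One 1:1 outgroup ortholog per focal gene, at ancestral expression.

    Orthologs of focal X genes land on outgroup autosomes 1 and 4 (the
    chicken proto-X arrangement); orthologs of focal autosomal genes are
    spread over outgroup autosomes.  Outgroup expression is the focal
    ancestral (pre-compensation, pre-silencing) level times a global species
    scale factor times log-normal noise, so ground-truth X:XX equals
    ``compensation_factor`` and AA:AA equals 1 after median scaling.
    """
    levels, _ = _deterministic_levels(annotation, params, ancestral=True)
    focal_is_x = annotation.is_x().to_numpy()
    og_ids = ["og_" + g for g in annotation.gene_ids]
    og_chroms = []
    i_x = i_a = 0
    for is_x in focal_is_x:
        if is_x:
            og_chroms.append(["1", "4"][i_x % 2])
            i_x += 1
        else:
            og_chroms.append(str(1 + (i_a % 22)))
            i_a += 1
    rng = _rng(params, "outgroup")
    slot_index: dict[str, int] = {}
    tss = np.empty(len(og_ids), dtype=np.int64)
    for i, chrom in enumerate(og_chroms):
        j = slot_index.get(chrom, 0)
        slot_index[chrom] = j + 1
        tss[i] = _SLOT_OFFSET + j * _GENE_SLOT + rng.integers(0, _SLOT_JITTER)
    og_annotation = GeneAnnotation(
        pd.DataFrame(
            {
                "chromosome": og_chroms,
                "biotype": "protein_coding",
                "tss": tss,
                "strand": np.where(rng.random(len(og_ids)) < 0.5, "+", "-"),
            },
            index=pd.Index(og_ids, name="gene_id"),
        )
    )
    samples = _sample_sheet(params, species="outgroup", prefix="og_")
    noise = np.exp(params.outgroup_noise_log_sd * rng.standard_normal(levels.shape))
    values = pd.DataFrame(
        levels.to_numpy() * params.species_scale * noise,
        index=pd.Index(og_ids, name="gene_id"),
        columns=samples.index,
    )
    pairs = pd.DataFrame(
        {
            "focal_gene": annotation.gene_ids,
            "outgroup_gene": og_ids,
            "focal_chrom": annotation.chromosome.to_numpy(),
            "outgroup_chrom": og_chroms,
        }
    )
    return (
        OrthologMap(pairs),
        ExpressionMatrix(values, og_annotation, samples),
        og_annotation,
    )


# ---------------------------------------------------------------------------
# proteome


def simulate_proteome(matrix: ExpressionMatrix, params: SimulationParams) -> ExpressionMatrix:
    """iBAQ-style protein abundances: mRNA**b times log-normal noise.

    ``proteome_exponent`` b < 1 compresses the dynamic range (translation
    buffering); zero mRNA always yields zero protein.
    """
    rng = _rng(params, "proteome")
    noise = np.exp(params.proteome_log_sd * rng.standard_normal(matrix.values.shape))
    values = (matrix.values ** params.proteome_exponent) * noise
    values[matrix.values == 0] = 0.0
    return ExpressionMatrix(values, matrix.annotation, matrix.samples)


# ---------------------------------------------------------------------------
# chromatin


def simulate_chromatin(
    annotation: GeneAnnotation, params: SimulationParams, n_epigenomes: int
) -> list[ChromatinSegmentation]:
    """Per-epigenome chromHMM-style segmentations with per-gene palettes.

    Each gene owns a fixed palette of non-quiescent states (size
    ``palette_size_x`` on X, ``palette_size_a`` on autosomes).  Per
    epigenome, each promoter is tiled with ``states_per_promoter`` distinct
    states drawn from its palette (optionally after a quiescent prefix
    covering ``promoter_quies_frac_*`` of the promoter); the rest of the
    genome is quiescent.  Across many epigenomes the union of observed
    states per gene recovers the palette size.
    """
    from .chromatin import promoter_intervals

    palette_rng = _rng(params, "palette")
    is_x = annotation.is_x()
    palettes = {}
    for gene_id in annotation.gene_ids:
        size = params.palette_size_x if is_x[gene_id] else params.palette_size_a
        palettes[gene_id] = palette_rng.choice(14, size=size, replace=False)
    promoters = promoter_intervals(annotation)
    promoters = promoters.sort_values(["chromosome", "start"])
    chrom_len = promoters.groupby("chromosome")["end"].max() + 1000

    segmentations = []
    for e in range(n_epigenomes):
        rng = _rng(params, f"chromatin-{e}")
        chroms, starts, ends, states = [], [], [], []

        def emit(chrom, start, end, state):
            if end > start:
                chroms.append(chrom)
                starts.append(start)
                ends.append(end)
                states.append(state)

        for chrom, sub in promoters.groupby("chromosome", sort=False):
            cursor = 0
            for row in sub.itertuples():
                emit(chrom, cursor, row.start, QUIESCENT)
                pos = row.start
                quies_frac = (
                    params.promoter_quies_frac_x
                    if is_x[row.Index]
                    else params.promoter_quies_frac_a
                )
                length = row.end - row.start
                q_len = int(round(quies_frac * length))
                if q_len:
                    emit(chrom, pos, pos + q_len, QUIESCENT)
                    pos += q_len
                palette = palettes[row.Index]
                k = min(params.states_per_promoter, len(palette))
                chosen = rng.choice(palette, size=k, replace=False)
                bounds = np.linspace(pos, row.end, k + 1).round().astype(int)
                for i in range(k):
                    emit(chrom, bounds[i], bounds[i + 1], CHROMHMM_STATES[chosen[i]])
                cursor = row.end
            emit(chrom, cursor, int(chrom_len[chrom]), QUIESCENT)
        df = pd.DataFrame({"chrom": chroms, "start": starts, "end": ends, "state": states})
        segmentations.append(ChromatinSegmentation(f"E{e:03d}", df))
    return segmentations


# ---------------------------------------------------------------------------
# file emission


def write_simulated_dataset(params: SimulationParams, outdir, n_epigenomes: int = 0) -> dict:
    """Generate a full dataset and write it in the package's TSV/BED dialects.

    Returns a manifest dict of the written paths.
    """
    from pathlib import Path

    from . import io as dio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_genome(params)
    matrix = simulate_expression(annotation, params)
    orthologs, og_matrix, og_annotation = simulate_outgroup(annotation, params)
    proteome = simulate_proteome(matrix, params)
    paths = {
        "annotation": outdir / "genes.tsv",
        "matrix": outdir / "expression.tsv",
        "samples": outdir / "samples.tsv",
        "orthologs": outdir / "orthologs.tsv",
        "outgroup_annotation": outdir / "outgroup_genes.tsv",
        "outgroup_matrix": outdir / "outgroup_expression.tsv",
        "outgroup_samples": outdir / "outgroup_samples.tsv",
        "proteome": outdir / "proteome.tsv",
    }
    dio.write_gene_annotation(annotation, paths["annotation"])
    dio.write_expression_matrix(matrix, paths["matrix"])
    dio.write_sample_sheet(matrix.samples, paths["samples"])
    dio.write_ortholog_map(orthologs, paths["orthologs"])
    dio.write_gene_annotation(og_annotation, paths["outgroup_annotation"])
    dio.write_expression_matrix(og_matrix, paths["outgroup_matrix"])
    dio.write_sample_sheet(og_matrix.samples, paths["outgroup_samples"])
    dio.write_expression_matrix(proteome, paths["proteome"])
    if n_epigenomes:
        seg_dir = outdir / "segmentations"
        seg_dir.mkdir(exist_ok=True)
        for seg in simulate_chromatin(annotation, params, n_epigenomes):
            path = seg_dir / f"{seg.epigenome_id}.bed"
            dio.write_segmentation(seg, path)
            paths[f"segmentation_{seg.epigenome_id}"] = path
    return {k: str(v) for k, v in paths.items()}
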