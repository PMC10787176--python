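"""Core data containers and TSV/BED readers for dosage-compensation analyses.

Everything downstream operates on three tables: a gene annotation
(chromosome, biotype, TSS, strand -- defining the X vs autosome partition),
a genes x samples expression matrix (FPKM or iBAQ; non-negative), and a
sample sheet (species, tissue, developmental stage, sex).  Cross-species
comparisons additionally consume a 1:1 ortholog table, and the chromatin
analysis consumes 4-column BED segmentations (one per epigenome).

Coordinates are 0-based half-open throughout (BED convention); the TSS is a
0-based position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("xdosage")

#: chromosome labels never counted as autosomes
SEX_CHROMOSOMES = frozenset({"X", "Y", "Z", "W"})
NON_NUCLEAR = frozenset({"MT", "M"})

ANNOTATION_COLUMNS = ["chromosome", "biotype", "tss", "strand"]
SAMPLE_COLUMNS = ["species", "tissue", "stage_label", "stage_rank", "sex"]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


def _strip_chr(label: str) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


class GeneAnnotation:
    """Per-gene chromosome, biotype, TSS and strand.

    The table is indexed by gene_id; gene ids must be unique and strand must
    be '+' or '-'.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
        if missing:
            raise DataError(f"annotation missing columns: {missing}")
        if table.index.has_duplicates:
            dupes = table.index[table.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene_id in annotation: {dupes[:5]}")
        bad_strand = set(table["strand"].unique()) - {"+", "-"}
        if bad_strand:
            raise DataError(f"invalid strand values: {sorted(bad_strand)}")
        if (table["tss"].astype(np.int64) < 0).any():
            raise DataError("negative TSS position in annotation")
        tbl = table.copy()
        tbl["chromosome"] = tbl["chromosome"].map(_strip_chr)
        tbl["tss"] = tbl["tss"].astype(np.int64)
        self.table = tbl

    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.table.index

    @property
    def chromosome(self) -> pd.Series:
        return self.table["chromosome"]

    def is_x(self) -> pd.Series:
        return self.chromosome == "X"

    def is_autosomal(self) -> pd.Series:
        return ~self.chromosome.isin(SEX_CHROMOSOMES | NON_NUCLEAR)

    @property
    def x_genes(self) -> pd.Index:
        return self.table.index[self.is_x()]

    @property
    def autosomal_genes(self) -> pd.Index:
        return self.table.index[self.is_autosomal()]

    def subset(self, gene_ids) -> "GeneAnnotation":
        return GeneAnnotation(self.table.loc[pd.Index(gene_ids)])


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with attached metadata.

    ``values`` is a DataFrame indexed by gene_id with sample_id columns;
    ``annotation`` covers every gene; ``samples`` is indexed by sample_id
    with species/tissue/stage_label/stage_rank/sex columns.
    """

    values: pd.DataFrame
    annotation: GeneAnnotation
    samples: pd.DataFrame = field(default=None)

    def __post_init__(self):
        # canonical axis names regardless of construction path
        self.values = self.values.rename_axis(index="gene_id", columns=None)
        vals = self.values.to_numpy()
        if vals.size and np.nanmin(vals) < 0:
            raise DataError("expression matrix contains negative values")
        unresolved = self.values.index.difference(self.annotation.gene_ids)
        if len(unresolved):
            raise DataError(
                f"{len(unresolved)} gene ids not resolvable in annotation, "
                f"e.g. {unresolved[:3].tolist()}"
            )
        if self.samples is None:
            self.samples = pd.DataFrame(
                {
                    "species": "unknown",
                    "tissue": "unknown",
                    "stage_label": "unknown",
                    "stage_rank": 0,
                    "sex": "unknown",
                },
                index=self.values.columns,
            )
        if not self.values.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_annotation(self) -> pd.DataFrame:
        return self.annotation.table.loc[self.values.index]

    def is_x(self) -> pd.Series:
        return self.gene_annotation["chromosome"] == "X"

    def is_autosomal(self) -> pd.Series:
        chrom = self.gene_annotation["chromosome"]
        return ~chrom.isin(SEX_CHROMOSOMES | NON_NUCLEAR)

    def select_samples(self, tissue=None, stage_label=None, sample_ids=None) -> list:
        """Sample ids matching the given context (AND of the constraints)."""
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if stage_label is not None:
            mask &= self.samples["stage_label"] == stage_label
        if sample_ids is not None:
            mask &= self.samples.index.isin(list(sample_ids))
        return self.samples.index[mask].tolist()

    def context_values(self, tissue=None, stage_label=None, sample_ids=None) -> pd.Series:
        """Per-gene expression in a context: the mean over the selected samples."""
        cols = self.select_samples(tissue, stage_label, sample_ids)
        if not cols:
            raise DataError(
                f"no samples match context tissue={tissue!r} stage={stage_label!r}"
            )
        return self.values[cols].mean(axis=1)

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = pd.Index(gene_ids)
        return ExpressionMatrix(self.values.loc[idx], self.annotation, self.samples)


@dataclass
class OrthologMap:
    """1:1 focal<->outgroup gene pairs with both chromosomes."""

    pairs: pd.DataFrame  # columns focal_gene, outgroup_gene, focal_chrom, outgroup_chrom
    relationship: str = "1:1"

    def __post_init__(self):
        for col in ("focal_gene", "outgroup_gene"):
            if self.pairs[col].duplicated().any():
                offenders = self.pairs[col][self.pairs[col].duplicated()].tolist()
                raise DataError(f"duplicated {col} violates 1:1 mapping: {offenders[:5]}")
        self.pairs = self.pairs.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ChromatinSegmentation:
    """One epigenome's chromHMM segmentation: disjoint labeled intervals.

    ``intervals`` has columns chrom, start, end, state with 0-based half-open
    coordinates; within a chromosome the intervals must not overlap.
    """

    epigenome_id: str
    intervals: pd.DataFrame

    def __post_init__(self):
        df = self.intervals
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise DataError(f"interval with start >= end at row {bad}")
        for chrom, sub in df.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise DataError(
                    f"overlapping intervals on chromosome {chrom} "
                    f"in epigenome {self.epigenome_id}"
                )
        self.intervals = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.intervals)


# ---------------------------------------------------------------------------
# readers / writers


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chromosome": str})
    if "gene_id" not in df.columns:
        raise DataError(f"{path}: annotation TSV needs a gene_id column")
    return GeneAnnotation(df.set_index("gene_id"))


def write_gene_annotation(annotation: GeneAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in ["sample_id", *SAMPLE_COLUMNS] if c not in df.columns]
    if missing:
        raise DataError(f"{path}: sample sheet missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise DataError(f"{path}: duplicate sample_id in sample sheet")
    df = df.set_index("sample_id")
    df["stage_rank"] = df["stage_rank"].astype(int)
    return df


def load_expression_matrix(
    path,
    annotation: GeneAnnotation,
    sample_sheet=None,
    protein_coding_only: bool = True,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene_id, header of sample ids).

    Genes absent from the annotation are dropped (with a logged count);
    malformed numeric cells raise a parse error naming the offending
    row/column; duplicate gene ids are an error.  With
    ``protein_coding_only`` (the default) the matrix is restricted to
    protein-coding genes, the convention for X:AA work.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.columns[0] != "gene_id":
        raise DataError(f"{path}: first column must be 'gene_id', got {raw.columns[0]!r}")
    if raw["gene_id"].duplicated().any():
        dupes = raw["gene_id"][raw["gene_id"].duplicated()].tolist()
        raise DataError(f"{path}: duplicate gene_id rows: {dupes[:5]}")
    raw = raw.set_index("gene_id")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise DataError(
            f"{path}: cannot parse value {raw.iat[r, c]!r} at "
            f"gene {raw.index[r]!r}, sample {raw.columns[c]!r}"
        )
    known = numeric.index.isin(annotation.gene_ids)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("%s: dropped %d genes absent from annotation", path, n_dropped)
    numeric = numeric.loc[known]
    if protein_coding_only:
        biotype = annotation.table.loc[numeric.index, "biotype"]
        n_nc = int((biotype != "protein_coding").sum())
        if n_nc:
            logger.info("%s: dropped %d non-protein-coding genes", path, n_nc)
        numeric = numeric.loc[biotype == "protein_coding"]
    samples = read_sample_sheet(sample_sheet) if sample_sheet is not None else None
    return ExpressionMatrix(numeric, annotation, samples)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write the values in the canonical TSV dialect (round-trips exactly)."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def load_ortholog_map(path) -> OrthologMap:
    """Read a 1:1 ortholog TSV (focal_gene, outgroup_gene, focal_chrom, outgroup_chrom)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    needed = ["focal_gene", "outgroup_gene", "focal_chrom", "outgroup_chrom"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"{path}: ortholog table missing columns {missing}")
    df = df[(df["focal_gene"] != "") & (df["outgroup_gene"] != "")]
    if df.empty:
        logger.warning("%s: empty ortholog map", path)
    df = df.copy()
    df["focal_chrom"] = df["focal_chrom"].map(_strip_chr)
    df["outgroup_chrom"] = df["outgroup_chrom"].map(_strip_chr)
    return OrthologMap(df[needed])


def write_ortholog_map(orthologs: OrthologMap, path) -> None:
    orthologs.pairs.to_csv(path, sep="\t", index=False)


def load_segmentation(path, epigenome_id: str | None = None) -> ChromatinSegmentation:
    """Read a 4-column BED segmentation (chrom, start, end, state).

    Coordinates are kept 0-based half-open exactly as in the file; unknown
    state labels are preserved verbatim.  start >= end raises an error with
    the line number; overlapping intervals violate the segmentation
    invariant and raise as well.
    """
    if epigenome_id is None:
        epigenome_id = str(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise DataError(f"{path}:{lineno}: expected 4 BED columns")
            chrom, start, end, state = parts[0], int(parts[1]), int(parts[2]), parts[3]
            if start >= end:
                raise DataError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            rows.append((chrom, start, end, state))
    if not rows:
        logger.warning("%s: empty segmentation", path)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
    if df.empty:
        df = df.astype({"start": np.int64, "end": np.int64})
    return ChromatinSegmentation(epigenome_id, df)


def write_segmentation(seg: ChromatinSegmentation, path) -> None:
    seg.intervals.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# expression filtering


def expressed_mask(values: pd.Series, cutoff: float, strict: bool = True) -> pd.Series:
    """Boolean mask of expressed genes: value > cutoff (strict) or >= cutoff.

    The strict form is the standard convention ("unexpressed" means value
    <= cutoff); strict=False exists only for edge-case exploration.
    """
    if cutoff < 0:
        raise DataError("cutoff must be non-negative")
    return values > cutoff if strict else values >= cutoff


def filter_expressed(
    matrix: ExpressionMatrix,
    cutoff: float,
    strict: bool = True,
    context: pd.Series | None = None,
) -> ExpressionMatrix:
    """Restrict a matrix to genes expressed above ``cutoff`` in a context.

    ``context`` is the per-gene value the filter is judged on (e.g. one
    tissue's mean); by default the mean over all samples.  Gene order is
    preserved.
    """
    if context is None:
        context = matrix.values.mean(axis=1)
    mask = expressed_mask(context.loc[matrix.gene_ids], cutoff, strict)
    return matrix.subset_genes(matrix.gene_ids[mask.to_numpy()])
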