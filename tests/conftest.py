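import numpy as np
import pandas as pd
import pytest

from xdosage import ExpressionMatrix, GeneAnnotation


def build_annotation(chroms: dict, tss: dict | None = None, strand: dict | None = None):
    """Annotation from a gene_id -> chromosome dict (TSS/strand optional)."""
    genes = list(chroms)
    table = pd.DataFrame(
        {
            "chromosome": [chroms[g] for g in genes],
            "biotype": "protein_coding",
            "tss": [(tss or {}).get(g, 10_000 * (i + 1)) for i, g in enumerate(genes)],
            "strand": [(strand or {}).get(g, "+") for g in genes],
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return GeneAnnotation(table)


def build_matrix(values: dict, chroms: dict, samples: pd.DataFrame | None = None):
    """ExpressionMatrix from gene_id -> row-of-values and gene_id -> chromosome."""
    df = pd.DataFrame.from_dict(values, orient="index", dtype=float)
    df.columns = [f"s{i + 1}" for i in range(df.shape[1])]
    df.index.name = "gene_id"
    if samples is not None:
        samples = samples.set_axis(df.columns)
    return ExpressionMatrix(df, build_annotation(chroms), samples)


def sample_sheet(tissues, stages=None):
    """Sample sheet with one sample per (tissue, stage) combination given."""
    stages = stages or [1] * len(tissues)
    return pd.DataFrame(
        {
            "species": "focal",
            "tissue": tissues,
            "stage_label": [f"s{r}" for r in stages],
            "stage_rank": stages,
            "sex": "unknown",
        }
    )


@pytest.fixture
def make_annotation():
    return build_annotation


@pytest.fixture
def make_matrix():
    return build_matrix


@pytest.fixture
def make_samples():
    return sample_sheet
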