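"""End-to-end orchestration: config -> report directory.

A run is described by a YAML config (paths or synthetic-data parameters,
stage toggles, cutoffs, bootstrap settings, one global seed) and produces
TSV tables plus a machine-readable manifest (seed, config hash, per-stage
row counts).  All randomness flows from the global seed through fixed
per-stage tags, so identical config+seed gives byte-identical numeric
output.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from . import orthologs as ortho
from . import ratios as rat
from . import specificity as spec
from . import stages as stg
from . import proteome as prot
from . import chromatin as chrom
from .io import DataError
from .simulate import SimulationParams, simulate_chromatin, simulate_expression, \
    simulate_genome, simulate_outgroup, simulate_proteome

ALL_STAGES = ["io", "ratios", "orthologs", "specificity", "stage", "proteome", "chromatin"]

_STAGE_INPUTS = {
    "ratios": ["annotation", "matrix", "samples"],
    "orthologs": ["annotation", "matrix", "samples", "orthologs",
                  "outgroup_matrix", "outgroup_samples", "outgroup_annotation"],
    "specificity": ["annotation", "matrix", "samples"],
    "stage": ["annotation", "matrix", "samples"],
    "proteome": ["annotation", "proteome", "samples"],
    "chromatin": ["annotation", "segmentation_dir"],
}


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    output_dir: str
    seed: int = 0
    synthetic: dict | None = None  # SimulationParams overrides (+ n_epigenomes)
    inputs: dict = field(default_factory=dict)
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    cutoff: float = 1.0
    cutoffs: list = field(default_factory=lambda: [0.0, 0.25, 0.5, 0.75, 1.0])
    n_boot: int = 1000
    level: float = 0.90
    tau_threshold: float = 0.8
    rho_threshold: float = 0.8
    p_threshold: float = 0.05
    n_bins: int = 100
    top_k: int = 25
    n_epigenomes: int = 10
    outgroup_rules: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        if "output_dir" not in raw:
            raise DataError("config must name an output_dir")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        """Documented fan-out: one 31-bit seed per stage from the global seed."""
        ss = np.random.SeedSequence((self.seed, zlib.crc32(stage.encode())))
        return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def preflight(config: RunConfig) -> None:
    """Every enabled stage's required inputs must resolve before execution."""
    if config.synthetic is not None:
        return
    for stage in config.stages:
        for key in _STAGE_INPUTS.get(stage, []):
            path = config.inputs.get(key)
            if path is None:
                raise DataError(f"stage {stage!r}: missing input field {key!r}")
            if not Path(path).exists():
                raise DataError(f"stage {stage!r}: input {key!r} not found: {path}")


def _load_dataset(config: RunConfig) -> dict:
    if config.synthetic is not None:
        overrides = dict(config.synthetic)
        n_epi = int(overrides.pop("n_epigenomes", config.n_epigenomes))
        params = SimulationParams(**{**overrides, "seed": overrides.get("seed", config.seed)})
        annotation = simulate_genome(params)
        matrix = simulate_expression(annotation, params)
        orthomap, og_matrix, og_annotation = simulate_outgroup(annotation, params)
        data = {
            "annotation": annotation,
            "matrix": matrix,
            "orthologs": orthomap,
            "outgroup_matrix": og_matrix,
            "outgroup_annotation": og_annotation,
            "proteome": simulate_proteome(matrix, params),
            "segmentations": (
                simulate_chromatin(annotation, params, n_epi)
                if "chromatin" in config.stages else []
            ),
            "params": params,
        }
        return data
    paths = config.inputs
    annotation = dio.read_gene_annotation(paths["annotation"])
    data = {"annotation": annotation}
    if "matrix" in paths:
        data["matrix"] = dio.load_expression_matrix(
            paths["matrix"], annotation, paths.get("samples")
        )
    if "orthologs" in paths:
        data["orthologs"] = dio.load_ortholog_map(paths["orthologs"])
        og_annotation = dio.read_gene_annotation(paths["outgroup_annotation"])
        data["outgroup_annotation"] = og_annotation
        data["outgroup_matrix"] = dio.load_expression_matrix(
            paths["outgroup_matrix"], og_annotation, paths.get("outgroup_samples")
        )
    if "proteome" in paths:
        data["proteome"] = dio.load_expression_matrix(
            paths["proteome"], annotation, paths.get("samples")
        )
    if "segmentation_dir" in paths:
        beds = sorted(Path(paths["segmentation_dir"]).glob("*.bed"))
        data["segmentations"] = [dio.load_segmentation(p, p.stem) for p in beds]
    return data


def run_full_analysis(config: RunConfig) -> Path:
    """Execute the enabled stages in dependency order; return the report dir.

    Any stage error aborts with the stage name attached; the manifest is
    written only for a fully successful run.
    """
    preflight(config)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages_completed": [],
        "row_counts": {},
    }
    current = None
    try:
        current = "io"
        data = _load_dataset(config)
        matrix = data.get("matrix")
        manifest["row_counts"]["io"] = {
            "genes": len(data["annotation"]),
            "samples": 0 if matrix is None else matrix.values.shape[1],
        }
        manifest["stages_completed"].append("io")
        tissues = (
            sorted(matrix.samples["tissue"].unique()) if matrix is not None else []
        )

        if "ratios" in config.stages:
            current = "ratios"
            rows = []
            for tissue in tissues:
                for est in rat.ratio_cutoff_series(matrix, config.cutoffs, tissue=tissue):
                    if est is None:
                        continue
                    boot = rat.bootstrap_xaa(
                        matrix, est.cutoff, tissue=tissue,
                        n_boot=config.n_boot, level=config.level,
                        seed=config.stage_seed(f"ratios/{tissue}/{est.cutoff}"),
                    )
                    rows.append(vars(boot))
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "xaa_ratios.tsv", sep="\t", index=False)
            manifest["row_counts"]["ratios"] = len(df)
            manifest["stages_completed"].append("ratios")

        if "orthologs" in config.stages:
            current = "orthologs"
            rules = ortho.OutgroupRules(
                allowed_x_chroms=frozenset(
                    map(str, config.outgroup_rules.get("allowed_x_chroms", []))
                ),
                excluded_chroms=frozenset(
                    map(str, config.outgroup_rules.get("excluded_chroms", ["Z", "W"]))
                ),
                x_as_autosome=bool(config.outgroup_rules.get("x_as_autosome", False)),
            )
            rows = []
            for tissue in tissues:
                est = ortho.xxx_pipeline(
                    data["orthologs"], matrix, data["outgroup_matrix"],
                    rules=rules, cutoff=config.cutoff, tissue=tissue,
                    outgroup_annotation=data.get("outgroup_annotation"),
                )
                rows.append(vars(est))
            df = pd.DataFrame(rows)
            df.to_csv(outdir / "xxx_ratios.tsv", sep="\t", index=False)
            manifest["row_counts"]["orthologs"] = len(df)
            manifest["stages_completed"].append("orthologs")

        if "specificity" in config.stages:
            current = "specificity"
            table = spec.tissue_mean_expression(matrix)
            taus = spec.tau_table(table)
            assign = spec.max_tissue_assignment(table)
            per_gene = assign.join(taus)
            per_gene.to_csv(outdir / "specificity.tsv", sep="\t", index_label="gene_id")
            _, fractions = spec.tissue_specific_genes(
                table, data["annotation"], config.tau_threshold
            )
            fractions.to_csv(outdir / "tissue_specific_fraction_x.tsv", sep="\t")
            manifest["row_counts"]["specificity"] = len(per_gene)
            manifest["stages_completed"].append("specificity")

        if "stage" in config.stages:
            current = "stage"
            frames = []
            sweeps = []
            for tissue in tissues:
                res = stg.stage_correlation(matrix, tissue)
                pos, neg = stg.classify_stage_correlated(
                    res, config.rho_threshold, config.p_threshold
                )
                res = res.assign(
                    tissue=tissue,
                    cls=np.select(
                        [res.index.isin(pos), res.index.isin(neg)],
                        ["positive", "negative"], default="none",
                    ),
                )
                frames.append(res)
                sweep = stg.xlinked_fraction_by_threshold(res, data["annotation"])
                sweeps.append(sweep.assign(tissue=tissue))
            pd.concat(frames).to_csv(
                outdir / "stage_correlation.tsv", sep="\t", index_label="gene_id"
            )
            pd.concat(sweeps).to_csv(outdir / "stage_sweep.tsv", sep="\t", index=False)
            manifest["row_counts"]["stage"] = sum(map(len, frames))
            manifest["stages_completed"].append("stage")

        if "proteome" in config.stages:
            current = "proteome"
            pmat = data["proteome"]
            values = pmat.values.mean(axis=1)
            x_vals = values[pmat.is_x()]
            a_vals = values[pmat.is_autosomal()]
            n_bins = min(config.n_bins, len(x_vals), len(a_vals))
            top_k = min(config.top_k, n_bins)
            x_bins = prot.quantile_bins(x_vals, n_bins, "X")
            a_bins = prot.quantile_bins(a_vals, n_bins, "autosomes")
            ratios, summary = prot.bin_matched_ratio(x_bins, a_bins, top_k)
            ratios.to_frame("xaa_ratio").to_csv(outdir / "proteome_bins.tsv", sep="\t")
            manifest["row_counts"]["proteome"] = len(ratios)
            manifest["proteome_summary"] = summary
            manifest["stages_completed"].append("proteome")

        if "chromatin" in config.stages:
            current = "chromatin"
            result = chrom.promoter_state_analysis(
                data["annotation"], data["segmentations"]
            )
            result["base_fractions"].to_csv(
                outdir / "state_base_fractions.tsv", sep="\t", index=False
            )
            div = result["diversity"]
            counts = div.pop("counts")
            counts.to_frame("n_states").to_csv(
                outdir / "state_counts.tsv", sep="\t", index_label="gene_id"
            )
            manifest["row_counts"]["chromatin"] = len(counts)
            manifest["state_diversity"] = div
            manifest["stages_completed"].append("chromatin")
    except Exception as exc:
        raise DataError(f"stage {current!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
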