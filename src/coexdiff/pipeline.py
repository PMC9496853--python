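"""End-to-end orchestration: preprocess -> batch-correct -> network ->
module selection -> hub genes -> enrichment -> replication.

The batch-corrected stacked matrix is used only to construct the network
and its modules; all module/gene statistics are computed on the original
per-dataset (uncorrected) matrices, so dataset-specific disease signal is
never diluted by the correction.  Identical config + seed produces byte
identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .batch import combat_adjust
from .containers import (
    ConfigurationError,
    ExpressionDataset,
    ModulePartition,
)
from .enrichment import GeneSetCollection, enrich, read_gmt
from .genes import gene_edge_reports, select_genes
from .io import (
    gene_reports_frame,
    module_reports_frame,
    read_annotation_tsv,
    read_expression_tsv,
    read_probe_map_tsv,
    write_frame,
    write_partition_tsv,
)
from .modules import evaluate_modules, module_direction, select_modules
from .network import (
    TreeCutParams,
    build_network,
    consensus_modules,
    default_tree_cut_grid,
)
from .preprocess import intersect_genes, preprocess_dataset
from .replication import replicate_genes
from .simulate import SimulationConfig, generate_study


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML file."""

    # inputs: either a simulation block or expression/annotation paths
    simulate: dict | None = None
    expression_paths: list[str] = field(default_factory=list)
    annotation_path: str | None = None
    probe_map_path: str | None = None
    gmt_path: str | None = None
    independent_path: str | None = None
    independent_annotation_path: str | None = None
    # preprocessing
    drop_fraction: float = 0.4
    log2: bool = False
    # network
    candidate_powers: list[int] = field(default_factory=lambda: list(range(1, 21)))
    r2_threshold: float = 0.8
    signed_adjacency: bool = False
    beta: int | None = None
    grid: list[dict] | None = None
    # selection thresholds
    de_alpha: float = 0.05
    dcoe_alpha: float = 0.05
    z_threshold: float = 2.0
    # bookkeeping
    seed: int = 0
    outdir: str = "coexdiff_out"

    def validate(self) -> None:
        if self.simulate is None:
            if not self.expression_paths:
                raise ConfigurationError("expression_paths is required when no "
                                         "simulate block is given")
            if self.annotation_path is None:
                raise ConfigurationError("annotation_path is required")
            for name in ("annotation_path", "probe_map_path", "gmt_path",
                         "independent_path", "independent_annotation_path"):
                p = getattr(self, name)
                if p is not None and not Path(p).exists():
                    raise ConfigurationError(f"{name} does not exist: {p}")
            for p in self.expression_paths:
                if not Path(p).exists():
                    raise ConfigurationError(f"expression_paths entry missing: {p}")
        if not 0.0 <= self.drop_fraction < 1.0:
            raise ConfigurationError("drop_fraction must lie in [0, 1)")
        for name in ("de_alpha", "dcoe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{name} must lie in (0, 1)")
        if self.z_threshold <= 0:
            raise ConfigurationError("z_threshold must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def tree_cut_grid(self) -> list[TreeCutParams]:
        if self.grid is None:
            return default_tree_cut_grid()
        return [TreeCutParams(**case) for case in self.grid]


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    datasets: dict[str, ExpressionDataset]
    corrected: pd.DataFrame
    beta: int
    partition: ModulePartition
    stability: pd.DataFrame
    module_reports: list
    selected_modules: list
    gene_reports: dict[str, list]
    selected_genes: dict[str, list[str]]
    enrichment: pd.DataFrame | None
    replication: dict[str, object]


def run_study(
    datasets: list[ExpressionDataset],
    config: PipelineConfig,
    probe_map: dict[str, str] | None = None,
    gene_sets: dict[str, list[str]] | None = None,
    independent: ExpressionDataset | None = None,
) -> PipelineResult:
    """Run the full analysis on in-memory datasets."""
    config.validate()
    prepped = [
        preprocess_dataset(
            ds,
            drop_fraction=config.drop_fraction,
            probe_map=probe_map,
            log2=config.log2,
        )
        for ds in datasets
    ]
    prepped = intersect_genes(prepped)
    by_id = {ds.batch.iloc[0]: ds for ds in prepped}

    stacked = pd.concat([ds.values for ds in prepped], axis=1)
    batch = pd.concat([ds.batch for ds in prepped])
    condition = pd.concat([ds.condition for ds in prepped])
    corrected, _ = combat_adjust(stacked, batch, covariates=condition)

    genes = list(corrected.index)
    net = build_network(
        corrected.to_numpy(dtype=float),
        genes,
        candidate_powers=tuple(config.candidate_powers),
        r2_threshold=config.r2_threshold,
        signed_adjacency=config.signed_adjacency,
        beta=config.beta,
    )
    partition, stability = consensus_modules(
        net.dissimilarity, genes, config.tree_cut_grid()
    )

    reports = evaluate_modules(
        by_id, partition, net.beta, signed_adjacency=config.signed_adjacency
    )
    selected = select_modules(
        reports, de_alpha=config.de_alpha, dcoe_alpha=config.dcoe_alpha
    )

    gene_reports: dict[str, list] = {}
    selected_genes: dict[str, list[str]] = {}
    for rep in selected:
        module_genes = partition.members(rep.label)
        greps = gene_edge_reports(
            by_id, module_genes, net.beta, signed_adjacency=config.signed_adjacency
        )
        hits = select_genes(
            greps,
            module_direction=module_direction(rep),
            module_expression_direction=rep.expression_direction,
            z_threshold=config.z_threshold,
        )
        gene_reports[rep.label] = greps
        selected_genes[rep.label] = [g.gene for g in hits]

    enrichment_table = None
    all_hits = sorted({g for gs in selected_genes.values() for g in gs})
    if gene_sets is not None and all_hits:
        collection = GeneSetCollection(sets=gene_sets, universe=genes)
        enrichment_table = enrich(all_hits, collection)

    replication: dict[str, object] = {}
    if independent is not None:
        for rep in selected:
            greps = gene_reports[rep.label]
            candidates = [g for g in greps if g.selected]
            if not candidates:
                continue
            replication[rep.label] = replicate_genes(
                candidates,
                independent,
                partition.members(rep.label),
                derivation_direction=module_direction(rep),
                derivation_expression_direction=rep.expression_direction,
            )

    return PipelineResult(
        datasets=by_id,
        corrected=corrected,
        beta=net.beta,
        partition=partition,
        stability=stability,
        module_reports=reports,
        selected_modules=selected,
        gene_reports=gene_reports,
        selected_genes=selected_genes,
        enrichment=enrichment_table,
        replication=replication,
    )


def _config_hash(config: PipelineConfig) -> str:
    fields = asdict(config)
    fields.pop("outdir", None)  # output location is not part of run identity
    canon = json.dumps(fields, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based entry point: load/simulate inputs, run, write reports.

    Returns the run manifest (also written to ``manifest.json``).
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    try:
        if config.simulate is not None:
            sim = SimulationConfig(**{**config.simulate, "seed": config.seed})
            study = generate_study(sim)
            datasets = study.datasets
        else:
            ann = read_annotation_tsv(config.annotation_path)
            datasets = [
                read_expression_tsv(p, ann) for p in config.expression_paths
            ]
        probe_map = (
            read_probe_map_tsv(config.probe_map_path)
            if config.probe_map_path
            else None
        )
        gene_sets = read_gmt(config.gmt_path) if config.gmt_path else None
        independent = None
        if config.independent_path:
            iann = read_annotation_tsv(
                config.independent_annotation_path or config.annotation_path
            )
            independent = read_expression_tsv(config.independent_path, iann)

        result = run_study(
            datasets,
            config,
            probe_map=probe_map,
            gene_sets=gene_sets,
            independent=independent,
        )

        write_partition_tsv(outdir / "modules.tsv", result.partition)
        write_frame(outdir / "stability.tsv", result.stability)
        write_frame(
            outdir / "module_reports.tsv",
            module_reports_frame(result.module_reports),
        )
        gene_frames = [
            gene_reports_frame(reps, module)
            for module, reps in sorted(result.gene_reports.items())
        ]
        write_frame(
            outdir / "gene_reports.tsv",
            pd.concat(gene_frames, ignore_index=True)
            if gene_frames
            else pd.DataFrame(
                columns=[
                    "module", "gene", "dataset", "edges_disease",
                    "edges_control", "delta", "z", "log2fc", "p",
                    "selected", "direction",
                ]
            ),
        )
        if result.enrichment is not None:
            write_frame(outdir / "enrichment.tsv", result.enrichment)
        for module, rep in sorted(result.replication.items()):
            write_frame(outdir / f"replication_{module}.tsv", rep.table)

        manifest = {
            "config_hash": _config_hash(config),
            "seed": config.seed,
            "version": __version__,
            "beta": result.beta,
            "counts": {
                "genes": len(result.partition.genes),
                "modules": len(result.partition.module_labels()),
                "unassigned": result.partition.n_unassigned(),
                "selected_modules": len(result.selected_modules),
                "selected_genes": sum(
                    len(v) for v in result.selected_genes.values()
                ),
                "replicated_genes": sum(
                    int(rep.table["replicated"].sum())
                    for rep in result.replication.values()
                ),
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True) + "\n"
        )
        return manifest
    except Exception as exc:  # noqa: BLE001 - stage-named abort marker
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
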