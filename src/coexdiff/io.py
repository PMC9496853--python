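"""TSV/JSON readers and writers for datasets, truth and stage reports.

All writers use a fixed float format so identical runs produce byte
identical files.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .containers import ExpressionDataset, ModulePartition, ValidationError
from .genes import GeneEdgeReport
from .modules import ModuleReport
from .simulate import SimulatedStudy

FLOAT_FMT = "%.10g"


def write_expression_tsv(path, ds: ExpressionDataset) -> None:
    ds.values.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def write_annotation_tsv(path, datasets: list[ExpressionDataset]) -> None:
    rows = []
    for ds in datasets:
        for s in ds.sample_ids:
            rows.append(
                {"sample": s, "condition": ds.condition[s], "batch": ds.batch[s]}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, annotation: pd.DataFrame) -> ExpressionDataset:
    """Read one expression TSV; sample annotations come from a shared table
    with columns sample/condition/batch."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    ann = annotation.set_index("sample") if "sample" in annotation.columns else annotation
    missing = [s for s in values.columns if s not in ann.index]
    if missing:
        raise ValidationError(f"samples without annotation: {missing[:5]}")
    sub = ann.loc[values.columns]
    return ExpressionDataset(values, sub["condition"], sub["batch"])


def read_annotation_tsv(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample", "condition", "batch"}
    if not need.issubset(ann.columns):
        raise ValidationError(f"annotation needs columns {sorted(need)}")
    return ann


def read_probe_map_tsv(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str, header=None, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_truth_json(path, study: SimulatedStudy) -> None:
    truth = {
        "modules": {m: study.truth_modules.members(m)
                    for m in study.truth_modules.module_labels()},
        "dcoe_modules": study.truth_dcoe,
        "de_modules": [[m, s] for m, s in study.truth_de],
        "hub_genes": study.truth_hubs,
    }
    Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True) + "\n")


def write_study(outdir, study: SimulatedStudy) -> list[Path]:
    """Write a simulated study as TSVs plus a truth JSON; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ds in study.datasets:
        ds_id = ds.batch.iloc[0]
        p = outdir / f"expression_{ds_id}.tsv"
        write_expression_tsv(p, ds)
        paths.append(p)
    p = outdir / "samples.tsv"
    write_annotation_tsv(p, study.datasets)
    paths.append(p)
    p = outdir / "truth.json"
    write_truth_json(p, study)
    paths.append(p)
    return paths


def write_partition_tsv(path, partition: ModulePartition) -> None:
    pd.DataFrame(
        {"gene": partition.genes, "module": partition.labels.to_numpy()}
    ).to_csv(path, sep="\t", index=False)


def module_reports_frame(reports: list[ModuleReport]) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for ds_id in rep.de:
            beta, p = rep.de[ds_id]
            t, praw, bonf, direction = rep.dcoe[ds_id]
            rows.append(
                {
                    "module": rep.label,
                    "dataset": ds_id,
                    "size": rep.size,
                    "de_beta": beta,
                    "de_p": p,
                    "dcoe_t": t,
                    "dcoe_p": praw,
                    "dcoe_p_bonf": bonf,
                    "dcoe_direction": direction,
                    "expression_direction": rep.expression_direction,
                    "selected": rep.selected,
                    "concordant": rep.concordant,
                }
            )
    return pd.DataFrame(rows)


def gene_reports_frame(reports: list[GeneEdgeReport], module: str) -> pd.DataFrame:
    rows = []
    for rep in reports:
        for ds_id in rep.z:
            rows.append(
                {
                    "module": module,
                    "gene": rep.gene,
                    "dataset": ds_id,
                    "edges_disease": rep.edges_disease[ds_id],
                    "edges_control": rep.edges_control[ds_id],
                    "delta": rep.delta[ds_id],
                    "z": rep.z[ds_id],
                    "log2fc": rep.log2fc[ds_id],
                    "p": rep.p[ds_id],
                    "selected": rep.selected,
                    "direction": rep.direction,
                }
            )
    return pd.DataFrame(rows)


def write_frame(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)
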