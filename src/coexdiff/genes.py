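"""Differential-hub gene identification inside selected modules.

Within a selected module, an "interaction" (edge) between two genes is
called when their TOM dissimilarity is extreme: below the matrix's mean
minus three SDs (computed separately for the disease and the control
dissimilarity matrix).  Per gene, the difference in edge counts between
conditions is standardized within the module (Z-score) and genes with
|Z| >= 2 in at least one dataset, a Z sign matching the module's GOC/LOC
direction, and fold-change signs consistent across datasets and with the
module's expression direction are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import CONTROL, DISEASE, ExpressionDataset, ValidationError
from .diffexpr import moderated_de
from .modules import GOC, LOC
from .network import bicor_matrix, signed_tom, soft_adjacency


@dataclass
class GeneEdgeReport:
    """Per-gene edge counts, Z-scores and fold changes across datasets."""

    gene: str
    # dataset -> values
    edges_disease: dict[str, int] = field(default_factory=dict)
    edges_control: dict[str, int] = field(default_factory=dict)
    delta: dict[str, int] = field(default_factory=dict)
    z: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    selected: bool = False
    direction: str = ""  # "gain" / "loss"


def call_edges(dissimilarity: np.ndarray) -> np.ndarray:
    """Boolean edge matrix: dissimilarity < (mean - 3 SD) of the upper triangle.

    The threshold uses the off-diagonal upper-triangle values only (each
    pair counted once, sample SD).  The diagonal carries no edges.  A
    degenerate constant matrix yields zero edges (strict inequality).
    """
    d = np.asarray(dissimilarity, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValidationError("edge calling needs >= 3 genes")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("dissimilarity must be symmetric")
    iu = np.triu_indices(n, k=1)
    vals = d[iu]
    tau = vals.mean() - 3.0 * vals.std(ddof=1)
    edges = d < tau
    np.fill_diagonal(edges, False)
    return edges & edges.T


def delta_edge_z(
    edges_disease: np.ndarray, edges_control: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene edge-count difference and its within-module Z-score.

    Z uses the population SD so that Z has mean 0 and SD exactly 1 whenever
    the deltas are not all equal; an all-equal module gives all-zero Z.
    """
    ed = np.asarray(edges_disease, dtype=bool)
    ec = np.asarray(edges_control, dtype=bool)
    if ed.shape != ec.shape:
        raise ValidationError("edge matrices must cover the same genes")
    delta = ed.sum(axis=1).astype(int) - ec.sum(axis=1).astype(int)
    sd = delta.std(ddof=0)
    if sd == 0:
        return delta, np.zeros_like(delta, dtype=float)
    return delta, (delta - delta.mean()) / sd


def gene_edge_reports(
    datasets: dict[str, ExpressionDataset],
    module_genes: list[str],
    beta: int,
    signed_adjacency: bool = False,
) -> list[GeneEdgeReport]:
    """Edge counts, Z-scores and module-restricted DE for every module gene.

    Per dataset and condition the module submatrix is taken through
    bicor -> power ``beta`` -> signed TOM -> dissimilarity, edges are called
    at the mean - 3 SD threshold of that matrix, and the per-gene edge-count
    change is standardized within the module.
    """
    reports = {g: GeneEdgeReport(gene=g) for g in module_genes}
    for ds_id, ds in datasets.items():
        sub = ds.subset_genes([g for g in module_genes if g in ds.values.index])
        edge_mats = {}
        for cond in (DISEASE, CONTROL):
            part = sub.subset_condition(cond)
            corr = bicor_matrix(part.values.to_numpy(dtype=float))
            adj = soft_adjacency(corr, beta, signed=signed_adjacency)
            edge_mats[cond] = call_edges(1.0 - signed_tom(adj))
        delta, z = delta_edge_z(edge_mats[DISEASE], edge_mats[CONTROL])
        de = moderated_de(sub)
        for i, g in enumerate(sub.gene_ids):
            rep = reports[g]
            rep.edges_disease[ds_id] = int(edge_mats[DISEASE][i].sum())
            rep.edges_control[ds_id] = int(edge_mats[CONTROL][i].sum())
            rep.delta[ds_id] = int(delta[i])
            rep.z[ds_id] = float(z[i])
            rep.log2fc[ds_id] = float(de.table["logFC"].iloc[i])
            rep.p[ds_id] = float(de.table["p"].iloc[i])
    return list(reports.values())


def select_genes(
    reports: list[GeneEdgeReport],
    module_direction: str,
    module_expression_direction: str,
    z_threshold: float = 2.0,
) -> list[GeneEdgeReport]:
    """Flag differential-hub genes of a module.

    A gene is selected when |Z| >= ``z_threshold`` in at least one dataset
    with the Z sign matching the module's connectivity direction (positive
    for GOC, negative for LOC), its fold-change sign is identical in every
    dataset, and that sign matches the module's expression direction ("up"
    -> positive, "down" -> negative).
    """
    want_sign = 1.0 if module_direction == GOC else -1.0
    want_fc = 1.0 if module_expression_direction == "up" else -1.0
    for rep in reports:
        z_ok = any(
            abs(z) >= z_threshold and np.sign(z) == want_sign
            for z in rep.z.values()
        )
        fcs = list(rep.log2fc.values())
        fc_signs = {np.sign(f) for f in fcs}
        fc_ok = (
            len(fc_signs) == 1
            and fc_signs.pop() == want_fc
        )
        rep.selected = bool(z_ok and fc_ok)
        if rep.selected:
            rep.direction = "gain" if want_sign > 0 else "loss"
    return [r for r in reports if r.selected]
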