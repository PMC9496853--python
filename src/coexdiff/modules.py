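"""Disease-related module selection by the dual DE + DcoE criterion.

A module passes when (i) its eigengene is associated with disease status
(DE criterion: OLS of the module eigengene on the disease indicator,
p < alpha in at least one dataset) and (ii) the intramodular connectivity of
its genes differs between condition-specific networks with a consistent
direction in every dataset (DcoE criterion: paired t-test, Bonferroni
p < 0.05).  GOC/LOC = gain/loss of connectivity, the sign of the mean
disease-minus-control connectivity difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    CONTROL,
    DISEASE,
    ExpressionDataset,
    ModulePartition,
    ValidationError,
)
from .network import bicor_matrix, soft_adjacency

GOC = "GOC"
LOC = "LOC"


@dataclass
class ModuleReport:
    """Per-module DE and DcoE statistics across datasets."""

    label: str
    size: int
    de: dict[str, tuple[float, float]] = field(default_factory=dict)
    # dataset -> (t, raw p, bonferroni p, direction)
    dcoe: dict[str, tuple[float, float, float, str]] = field(default_factory=dict)
    expression_direction: str = ""  # "up" / "down"
    selected: bool = False
    concordant: bool | None = None


def module_eigengene(
    ds: ExpressionDataset, genes: list[str]
) -> tuple[pd.Series, float]:
    """First principal component of the standardized module submatrix.

    Returns the per-sample eigengene scores (unit norm, sign-aligned so the
    eigengene correlates non-negatively with the module's mean standardized
    expression) and the fraction of variance it explains.
    """
    present = [g for g in genes if g in ds.values.index]
    if len(present) < 2:
        raise ValidationError("module eigengene needs >= 2 genes")
    x = ds.values.loc[present].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    mean_profile = z.mean(axis=0)
    if me @ mean_profile < 0:
        me = -me
    var_explained = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    return pd.Series(me, index=ds.values.columns, name="ME"), var_explained


def de_criterion(me: pd.Series, status: pd.Series) -> tuple[float, float]:
    """OLS of the module eigengene on the disease indicator -> (beta, p)."""
    status = pd.Series(status).loc[me.index]
    ind = (status == DISEASE).to_numpy(float)
    if ind.sum() == 0 or ind.sum() == len(ind):
        raise ValidationError("both conditions must be present")
    y = me.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        import warnings

        warnings.warn("constant module eigengene", stacklevel=2)
        return 0.0, 1.0
    res = stats.linregress(ind, y)
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 0.0
    return float(res.slope), p


def intramodular_connectivity(
    adjacency: np.ndarray, genes_all: list[str], module_genes: list[str]
) -> pd.Series:
    """Per-gene sum of adjacency to the other module genes (self excluded)."""
    pos = {g: i for i, g in enumerate(genes_all)}
    missing = [g for g in module_genes if g not in pos]
    if missing:
        raise ValidationError(f"genes outside the universe: {missing[:5]}")
    idx = [pos[g] for g in module_genes]
    sub = np.asarray(adjacency, dtype=float)[np.ix_(idx, idx)]
    k = sub.sum(axis=1) - np.diag(sub)
    return pd.Series(k, index=module_genes, name="kWithin")


def dcoe_criterion(
    k_disease: pd.Series, k_control: pd.Series, n_modules_tested: int
) -> tuple[float, float, float, str]:
    """Paired t-test on per-gene connectivity (disease - control).

    Returns (t, raw p, Bonferroni p over ``n_modules_tested``, direction)
    where direction is GOC when the mean difference is positive, else LOC.
    """
    kd = np.asarray(k_disease, dtype=float)
    kc = np.asarray(k_control.loc[k_disease.index] if isinstance(k_control, pd.Series) else k_control, dtype=float)
    if kd.shape != kc.shape or kd.size < 3:
        raise ValidationError("paired vectors of length >= 3 required")
    diff = kd - kc
    if np.allclose(diff, 0.0):
        return 0.0, 1.0, 1.0, LOC
    t, p = stats.ttest_rel(kd, kc)
    direction = GOC if diff.mean() > 0 else LOC
    bonf = min(1.0, float(p) * n_modules_tested)
    return float(t), float(p), bonf, direction


def condition_adjacency(
    ds: ExpressionDataset, beta: int, signed: bool = False
) -> dict[str, np.ndarray]:
    """Condition-specific soft-thresholded adjacency matrices of a dataset."""
    out = {}
    for cond in (DISEASE, CONTROL):
        sub = ds.subset_condition(cond)
        corr = bicor_matrix(sub.values.to_numpy(dtype=float))
        out[cond] = soft_adjacency(corr, beta, signed=signed)
    return out


def evaluate_modules(
    datasets: dict[str, ExpressionDataset],
    partition: ModulePartition,
    beta: int,
    signed_adjacency: bool = False,
) -> list[ModuleReport]:
    """Compute DE and DcoE statistics for every non-grey module.

    Each dataset contributes one eigengene regression and one paired
    connectivity test per module; connectivity comes from condition-specific
    adjacency matrices rebuilt with the combined network's power ``beta``.
    Bonferroni correction spans the number of modules tested.
    """
    labels = partition.module_labels()
    n_tested = len(labels)
    reports = [
        ModuleReport(label=m, size=len(partition.members(m))) for m in labels
    ]
    by_label = {r.label: r for r in reports}
    for ds_id, ds in datasets.items():
        adj = condition_adjacency(ds, beta, signed=signed_adjacency)
        genes_all = ds.gene_ids
        for m in labels:
            genes = [g for g in partition.members(m) if g in ds.values.index]
            rep = by_label[m]
            me, _ = module_eigengene(ds, genes)
            rep.de[ds_id] = de_criterion(me, ds.condition)
            kd = intramodular_connectivity(adj[DISEASE], genes_all, genes)
            kc = intramodular_connectivity(adj[CONTROL], genes_all, genes)
            rep.dcoe[ds_id] = dcoe_criterion(kd, kc, n_tested)
    for rep in reports:
        mean_beta = np.mean([b for b, _ in rep.de.values()])
        rep.expression_direction = "up" if mean_beta > 0 else "down"
    return reports


def select_modules(
    reports: list[ModuleReport],
    de_alpha: float = 0.05,
    dcoe_alpha: float = 0.05,
) -> list[ModuleReport]:
    """Apply the dual criterion and return the selected reports.

    Selected iff the DE p-value is below ``de_alpha`` in at least one
    dataset AND the DcoE Bonferroni p-value is below ``dcoe_alpha`` with the
    same connectivity direction in every dataset.  Whether the expression
    and connectivity directions agree (up with GOC / down with LOC) is
    recorded in ``concordant`` but not required.
    """
    for rep in reports:
        de_ok = any(p < de_alpha for _, p in rep.de.values())
        dirs = {d for *_, d in rep.dcoe.values()}
        dcoe_ok = (
            len(dirs) == 1
            and all(bonf < dcoe_alpha for _, _, bonf, _ in rep.dcoe.values())
        )
        rep.selected = bool(de_ok and dcoe_ok)
        if rep.selected:
            direction = dirs.pop()
            rep.concordant = (
                rep.expression_direction == "up" and direction == GOC
            ) or (rep.expression_direction == "down" and direction == LOC)
    return [r for r in reports if r.selected]


def module_direction(report: ModuleReport) -> str:
    """Consensus DcoE direction of a (selected) module."""
    dirs = {d for *_, d in report.dcoe.values()}
    if len(dirs) != 1:
        raise ValidationError("module has inconsistent DcoE directions")
    return dirs.pop()
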