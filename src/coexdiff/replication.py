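"""Replication of candidate modules and genes in an independent dataset.

Replication avoids re-deriving the whole network: within the candidate
module's gene list, condition-wise Spearman correlation matrices are built
in the independent dataset, per-gene connectivity is the (signed) sum of
correlations to module peers, and a gene replicates when both its
connectivity-change direction and its fold-change direction agree with the
derivation study.  Module-level GOC/LOC is a paired t-test on the per-gene
connectivity difference, the same machinery as derivation-side DcoE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .containers import CONTROL, DISEASE, ExpressionDataset, ValidationError
from .diffexpr import moderated_de
from .genes import GeneEdgeReport
from .modules import GOC, LOC, dcoe_criterion


@dataclass
class ReplicationReport:
    """Per-gene replication outcomes plus the module-level paired test."""

    table: pd.DataFrame  # gene, k_disease, k_control, delta_k, logFC, p, p_adj,
    #                      conn_direction, testable, conn_ok, fc_ok, replicated
    module_t: float
    module_p: float
    module_direction: str


def condition_rank_matrices(
    ds: ExpressionDataset, genes: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman correlation matrices over module genes, one per condition.

    Genes missing from the dataset are dropped with a warning; each
    condition needs at least 4 samples.
    """
    present = [g for g in genes if g in ds.values.index]
    missing = len(genes) - len(present)
    if missing:
        warnings.warn(f"{missing} module genes absent from dataset", stacklevel=2)
    if len(present) < 3:
        raise ValidationError("need >= 3 module genes present")
    out = []
    for cond in (DISEASE, CONTROL):
        sub = ds.subset_condition(cond).subset_genes(present)
        if sub.n_samples < 4:
            raise ValidationError(f"need >= 4 samples in condition {cond!r}")
        rho = spearmanr(sub.values.to_numpy(dtype=float), axis=1).statistic
        rho = np.atleast_2d(rho)
        out.append(pd.DataFrame(rho, index=present, columns=present))
    return out[0], out[1]


def _connectivity(rho: pd.DataFrame, use_abs: bool) -> pd.Series:
    m = rho.to_numpy(dtype=float).copy()
    if use_abs:
        m = np.abs(m)
    np.fill_diagonal(m, 0.0)
    return pd.Series(m.sum(axis=1), index=rho.index, name="k")


def replicate_genes(
    derivation: list[GeneEdgeReport],
    independent: ExpressionDataset,
    module_genes: list[str],
    derivation_direction: str,
    derivation_expression_direction: str,
    use_abs: bool = False,
    fc_alpha: float = 0.05,
) -> ReplicationReport:
    """Test derivation candidates in an independent dataset.

    ``derivation`` lists the candidate genes (their selection flags and
    directions from the derivation study); ``module_genes`` is the full
    module gene list used to build the rank-correlation connectivity.
    A candidate replicates when its connectivity change direction matches
    ``derivation_direction`` (GOC -> positive) and it is dysregulated in
    the independent dataset in the derivation direction (fold-change sign
    matches ``derivation_expression_direction`` with FDR-adjusted
    p < ``fc_alpha``; a sign flip alone would agree by chance half the
    time).  Genes absent from the independent dataset are marked
    untestable, not failed.
    """
    rho_d, rho_c = condition_rank_matrices(independent, module_genes)
    kd = _connectivity(rho_d, use_abs)
    kc = _connectivity(rho_c, use_abs)
    t, p, _, module_dir = dcoe_criterion(kd, kc, 1)

    present = list(rho_d.index)
    de = moderated_de(independent.subset_genes(present))
    want_conn = 1.0 if derivation_direction == GOC else -1.0
    want_fc = 1.0 if derivation_expression_direction == "up" else -1.0

    rows = []
    for rep in derivation:
        g = rep.gene
        testable = g in rho_d.index
        if testable:
            delta_k = float(kd[g] - kc[g])
            logfc = float(de.table.loc[g, "logFC"])
            padj = float(de.table.loc[g, "p_adj"])
            praw = float(de.table.loc[g, "p"])
            conn_ok = np.sign(delta_k) == want_conn and delta_k != 0.0
            fc_ok = np.sign(logfc) == want_fc and padj < fc_alpha
        else:
            delta_k = np.nan
            logfc = padj = praw = np.nan
            conn_ok = fc_ok = False
        rows.append(
            {
                "gene": g,
                "k_disease": float(kd[g]) if testable else np.nan,
                "k_control": float(kc[g]) if testable else np.nan,
                "delta_k": delta_k,
                "logFC": logfc,
                "p": praw,
                "p_adj": padj,
                "conn_direction": (
                    (GOC if delta_k > 0 else LOC) if testable else ""
                ),
                "testable": testable,
                "conn_ok": bool(conn_ok),
                "fc_ok": bool(fc_ok),
                "replicated": bool(testable and conn_ok and fc_ok),
            }
        )
    return ReplicationReport(
        table=pd.DataFrame(rows),
        module_t=t,
        module_p=p,
        module_direction=module_dir,
    )
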