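"""Normalization, variance filtering, probe collapsing and gene alignment.

The preprocessing order used by the pipeline is quantile-normalize ->
variance filter -> probe collapse, each step also usable on its own.  Data
are expected on the log2 scale; :func:`log2_transform` is provided for
linear-scale inputs but scale is never auto-detected.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ConfigurationError, ExpressionDataset, ValidationError


def log2_transform(values: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) helper for linear-scale matrices."""
    if (values < 0).any().any():
        raise ValidationError("negative values: input does not look linear-scale")
    return np.log2(values + 1.0)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common (row-mean) distribution.

    The reference distribution is the row-wise mean of the column-sorted
    matrix; each column's values are replaced by the reference values at
    their ranks.  Ties receive the average of the reference values at the
    tied ranks, so the operation is deterministic; on tie-free input every
    column's sorted values equal the reference exactly and the operation is
    idempotent.
    """
    if values.shape[1] < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    if values.isna().any().any():
        raise ValidationError("missing values are not allowed")
    x = values.to_numpy(dtype=float)
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    n = x.shape[0]
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, reference)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def filter_low_variance(
    ds: ExpressionDataset, drop_fraction: float = 0.4
) -> ExpressionDataset:
    """Drop the lowest ``drop_fraction`` of genes by cross-sample SD.

    Exactly ``ceil((1 - drop_fraction) * n_genes)`` genes are kept.  SD ties
    are broken by gene id so that the lexicographically larger id is kept.
    """
    if not 0.0 <= drop_fraction < 1.0:
        raise ConfigurationError("drop_fraction must lie in [0, 1)")
    n = ds.n_genes
    n_keep = math.ceil((1.0 - drop_fraction) * n)
    sd = ds.values.std(axis=1, ddof=1)
    order = sorted(ds.gene_ids, key=lambda g: (sd[g], g))
    dropped = set(order[: n - n_keep])
    kept = [g for g in ds.gene_ids if g not in dropped]
    return ds.subset_genes(kept)


def collapse_probes(
    values: pd.DataFrame, probe_map: dict[str, str]
) -> pd.DataFrame:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the probe with the largest mean expression across samples
    is retained (ties broken toward the lexicographically smallest probe
    id).  Every probe row must be mapped; the returned matrix is indexed by
    gene id in sorted order.
    """
    unmapped = [p for p in values.index if p not in probe_map]
    if unmapped:
        raise ValidationError(f"unmapped probes: {unmapped[:10]}")
    means = values.mean(axis=1)
    best: dict[str, str] = {}
    for probe in values.index:
        gene = probe_map[probe]
        cur = best.get(gene)
        if (
            cur is None
            or means[probe] > means[cur]
            or (means[probe] == means[cur] and probe < cur)
        ):
            best[gene] = probe
    genes = sorted(best)
    out = values.loc[[best[g] for g in genes]].copy()
    out.index = pd.Index(genes, name=values.index.name)
    return out


def intersect_genes(datasets: list[ExpressionDataset]) -> list[ExpressionDataset]:
    """Restrict every dataset to the common gene set, rows in identical order."""
    if len(datasets) < 2:
        raise ValidationError("need >= 2 datasets to intersect")
    common = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        common &= set(ds.gene_ids)
    if not common:
        raise ValidationError("gene intersection across datasets is empty")
    order = [g for g in datasets[0].gene_ids if g in common]
    return [ds.subset_genes(order) for ds in datasets]


def preprocess_dataset(
    ds: ExpressionDataset,
    drop_fraction: float = 0.4,
    probe_map: dict[str, str] | None = None,
    log2: bool = False,
) -> ExpressionDataset:
    """normalize -> filter -> (optionally) collapse, as one call."""
    values = ds.values
    if log2:
        values = log2_transform(values)
    values = quantile_normalize(values)
    ds = ExpressionDataset(values, ds.condition, ds.batch)
    ds = filter_low_variance(ds, drop_fraction)
    if probe_map is not None:
        collapsed = collapse_probes(ds.values, probe_map)
        ds = ExpressionDataset(collapsed, ds.condition, ds.batch)
    return ds
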