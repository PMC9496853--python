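"""Weighted co-expression network construction and module detection.

The network is built in the usual WGCNA sequence: robust pairwise
correlation (biweight midcorrelation), soft thresholding at a power chosen
for approximate scale-free topology (signed R^2 > 0.8), topological overlap
(signed TOM type), average-linkage clustering of 1 - TOM, and a top-down
hybrid dynamic tree cut with the PAM stage off, so genes that fit no branch
stay unassigned ("grey").  A consensus step reruns the cut over a grid of
tree-cut parameters and selects the case whose modules are stable in more
than half of the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import linregress

from .containers import (
    ConfigurationError,
    ModulePartition,
    ValidationError,
    color_labels,
)

#: deep_split -> branch-threshold interpolation fraction (more permissive /
#: more aggressive splitting as deep_split grows), following the hybrid
#: tree-cut convention.
_DEEP_SPLIT_FRAC = (0.64, 0.73, 0.82, 0.91, 0.95)


@dataclass
class TreeCutParams:
    """Hybrid tree-cut parameters (PAM stage off by default)."""

    min_module_size: int = 30
    deep_split: int = 2
    max_dissimilarity: float = 0.2
    pam_stage: bool = False

    def validate(self) -> None:
        if self.min_module_size < 2:
            raise ConfigurationError("min_module_size must be >= 2")
        if self.deep_split not in (0, 1, 2, 3, 4):
            raise ConfigurationError("deep_split must be in {0,...,4}")
        if not 0.0 < self.max_dissimilarity <= 1.0:
            raise ConfigurationError("max_dissimilarity must lie in (0, 1]")


@dataclass
class GeneNetwork:
    """Correlation, adjacency and TOM matrices over one gene universe."""

    genes: list[str]
    correlation: np.ndarray
    beta: int
    adjacency: np.ndarray
    tom: np.ndarray

    @property
    def dissimilarity(self) -> np.ndarray:
        return 1.0 - self.tom


def bicor_matrix(values: np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between all row pairs.

    Each row is centered at its median and weighted by the Tukey biweight
    w = (1-u^2)^2 for |u| < 1 with u = (x - median) / (9 * MAD).  Rows with
    zero MAD fall back to Pearson (mean-centering, unit weights) for every
    pair they participate in, since the biweight is undefined there.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[1] < 4:
        raise ValidationError("biweight midcorrelation needs >= 4 samples")
    med = np.median(x, axis=1, keepdims=True)
    dev = x - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    zero_mad = mad[:, 0] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        u = dev / (9.0 * mad)
    u[zero_mad] = 0.0
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1.0)
    xt = dev * w
    if zero_mad.any():
        xz = x[zero_mad]
        xt[zero_mad] = xz - xz.mean(axis=1, keepdims=True)
    norm = np.sqrt((xt**2).sum(axis=1, keepdims=True))
    norm[norm == 0] = 1.0  # constant rows: leave zero vector -> corr 0
    xn = xt / norm
    c = xn @ xn.T
    np.clip(c, -1.0, 1.0, out=c)
    np.fill_diagonal(c, 1.0)
    return c


def soft_adjacency(corr: np.ndarray, beta: int, signed: bool = False) -> np.ndarray:
    """Correlation -> adjacency via the power function.

    Unsigned (default): a = |r|^beta.  Signed variant: a = ((1+r)/2)^beta.
    """
    if signed:
        a = ((1.0 + corr) / 2.0) ** beta
    else:
        a = np.abs(corr) ** beta
    np.fill_diagonal(a, 1.0)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free fit index for a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width intervals;
    log10(frequency) is regressed on log10(mean connectivity per bin).  The
    returned index is -sign(slope) * R^2, so topologies with rising degree
    frequency (positive slope) score negatively.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < n_bins or np.ptp(k) == 0:
        return np.nan, np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, mean_k = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            freq.append(sel.mean())
            mean_k.append(k[sel].mean())
    if len(freq) < 3:
        return np.nan, np.nan
    res = linregress(np.log10(mean_k), np.log10(freq))
    return -np.sign(res.slope) * res.rvalue**2, res.slope


def pick_soft_threshold(
    corr: np.ndarray,
    candidate_powers=tuple(range(1, 21)),
    r2_threshold: float = 0.8,
    signed: bool = False,
    min_mean_k: float = 1.0,
) -> tuple[int, pd.DataFrame, bool]:
    """Choose the smallest power giving scale-free topology (R^2 > 0.8).

    Powers that collapse the network (mean connectivity below
    ``min_mean_k``) are excluded from selection: any thresholded network
    eventually looks scale-free once almost all edges vanish, so without
    the floor the rule degenerates.  Returns ``(beta, fit_table, warning)``;
    ``warning`` is set when no eligible candidate reaches the threshold
    (the best-fitting eligible power is returned) or when every fit is
    degenerate.
    """
    if any(b <= 0 for b in candidate_powers):
        raise ConfigurationError("candidate powers must be positive")
    rows = []
    for b in candidate_powers:
        a = soft_adjacency(corr, b, signed=signed)
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        fit, slope = scale_free_fit(k)
        rows.append(
            {"power": b, "sft_r2": fit, "slope": slope, "mean_k": k.mean()}
        )
    table = pd.DataFrame(rows)
    eligible = table["mean_k"] >= min_mean_k
    if not eligible.any():
        eligible = table.index == 0
    ok = eligible & (table["sft_r2"] > r2_threshold)
    if ok.any():
        beta = int(table.loc[ok, "power"].iloc[0])
        return beta, table, False
    warnings.warn(
        "no candidate power reached the scale-free fit threshold; "
        "returning the best-fitting power",
        stacklevel=2,
    )
    sub = table[eligible]
    if sub["sft_r2"].notna().any():
        beta = int(sub.loc[sub["sft_r2"].idxmax(), "power"])
    else:
        beta = int(sub["power"].iloc[0])
    return beta, table, True


def signed_tom(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix from an adjacency in [0, 1].

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    diagonal treated as zero internally and set to 1 in the result.
    """
    a = np.asarray(adjacency, dtype=float)
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValidationError("adjacency must be symmetric")
    if a.min() < -1e-12 or a.max() > 1 + 1e-12:
        raise ValidationError("adjacency entries must lie in [0, 1]")
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / den
    t = np.where(np.isfinite(t), t, 0.0)
    np.clip(t, 0.0, 1.0, out=t)
    np.fill_diagonal(t, 1.0)
    return (t + t.T) / 2.0


def build_network(
    values: np.ndarray,
    genes: list[str],
    candidate_powers=tuple(range(1, 21)),
    r2_threshold: float = 0.8,
    signed_adjacency: bool = False,
    beta: int | None = None,
) -> GeneNetwork:
    """bicor -> soft threshold -> signed TOM, as one call."""
    corr = bicor_matrix(values)
    if beta is None:
        beta, _, _ = pick_soft_threshold(
            corr, candidate_powers, r2_threshold, signed=signed_adjacency
        )
    adj = soft_adjacency(corr, beta, signed=signed_adjacency)
    tom = signed_tom(adj)
    return GeneNetwork(
        genes=list(genes), correlation=corr, beta=beta, adjacency=adj, tom=tom
    )


# ---------------------------------------------------------------------------
# hybrid dynamic tree cut
# ---------------------------------------------------------------------------

def _validate_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValidationError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValidationError("dissimilarity diagonal must be zero")
    return (d + d.T) / 2.0


def average_linkage(dissimilarity: np.ndarray) -> np.ndarray:
    """Average-linkage dendrogram of a gene dissimilarity matrix."""
    d = _validate_dissimilarity(dissimilarity)
    dc = d.copy()
    np.fill_diagonal(dc, 0.0)
    return linkage(squareform(dc, checks=False), method="average")


def _cut_from_linkage(
    link: np.ndarray, d: np.ndarray, genes: list[str], params: TreeCutParams
) -> ModulePartition:
    params.validate()
    n = len(genes)
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size: all grey", stacklevel=2)
        return color_labels([], genes)

    heights = link[:, 2]
    h_lo, h_hi = float(heights.min()), float(heights.max())
    cut_height = h_lo + (1.0 - params.max_dissimilarity) * (h_hi - h_lo)
    h_ref = float(np.quantile(heights, 0.05))
    h_ref = min(h_ref, cut_height)
    frac = _DEEP_SPLIT_FRAC[params.deep_split]
    max_core_scatter = h_ref + frac * (cut_height - h_ref)
    gap_thresh = 0.75 * (1.0 - frac) * (cut_height - h_ref)

    root = to_tree(link)

    leaves_cache: dict[int, list[int]] = {}

    def leaves(node) -> list[int]:
        if node.id not in leaves_cache:
            if node.is_leaf():
                leaves_cache[node.id] = [node.id]
            else:
                leaves_cache[node.id] = leaves(node.left) + leaves(node.right)
        return leaves_cache[node.id]

    # core scatter of a branch = mean merge height inside it, the same scale
    # as the cut height, so TOM dissimilarities compressed toward 1 are
    # handled the same way as spread-out ones
    scatter_cache: dict[int, tuple[int, float]] = {}

    def _merge_stats(node) -> tuple[int, float]:
        if node.is_leaf():
            return 0, 0.0
        if node.id not in scatter_cache:
            nl, sl = _merge_stats(node.left)
            nr, sr = _merge_stats(node.right)
            scatter_cache[node.id] = (nl + nr + 1, sl + sr + node.dist)
        return scatter_cache[node.id]

    def core_scatter(node) -> float:
        n_merges, total = _merge_stats(node)
        return total / n_merges if n_merges else 0.0

    def decide(node) -> list[list[int]]:
        idx = leaves(node)
        if len(idx) < params.min_module_size or node.is_leaf():
            return []
        left, right = node.left, node.right
        nl, nr = len(leaves(left)), len(leaves(right))
        child_h = max(
            left.dist if not left.is_leaf() else 0.0,
            right.dist if not right.is_leaf() else 0.0,
        )
        gap = node.dist - child_h
        if (
            nl >= params.min_module_size
            and nr >= params.min_module_size
            and gap >= gap_thresh
        ):
            mods = decide(left) + decide(right)
            if mods:
                return mods
        if core_scatter(node) <= max_core_scatter:
            return [idx]
        return decide(left) + decide(right)

    # branches that merge above the cut height are separate subproblems
    def collect(node) -> list[list[int]]:
        if not node.is_leaf() and node.dist > cut_height:
            return collect(node.left) + collect(node.right)
        return decide(node)

    groups_idx = collect(root)
    groups = [[genes[i] for i in idx] for idx in groups_idx]
    return color_labels(groups, genes)


def cut_modules(dissimilarity: np.ndarray, genes: list[str], params: TreeCutParams) -> ModulePartition:
    """Hybrid dynamic tree cut of a dissimilarity matrix into modules.

    Branches of the average-linkage dendrogram are decomposed top-down:
    a branch becomes a module when it is large enough
    (``min_module_size``) and tight enough (mean within-branch dissimilarity
    below a ``deep_split``-controlled core-scatter ceiling); sub-branches
    separated by a large merge gap are split further.  Genes on no
    qualifying branch, or merging only above the ``max_dissimilarity``-derived
    cut-height ceiling, are left "grey" (the PAM rescue stage is off).
    """
    d = _validate_dissimilarity(dissimilarity)
    link = average_linkage(d)
    return _cut_from_linkage(link, d, genes, params)


def default_tree_cut_grid() -> list[TreeCutParams]:
    """The robustness grid: sizes 50..100 x deep splits 0..4 x max
    dissimilarity {0.1, 0.2} = 60 cases."""
    return [
        TreeCutParams(min_module_size=s, deep_split=ds, max_dissimilarity=md)
        for s, ds, md in product(
            (50, 60, 70, 80, 90, 100), (0, 1, 2, 3, 4), (0.1, 0.2)
        )
    ]


def _jaccard(a: set, b: set) -> float:
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def consensus_modules(
    dissimilarity: np.ndarray,
    genes: list[str],
    grid: list[TreeCutParams] | None = None,
) -> tuple[ModulePartition, pd.DataFrame]:
    """Module partition most stable across a tree-cut parameter grid.

    Every grid case is cut; each module of each case is scored by the
    fraction of grid cases containing a module with Jaccard overlap >= 0.5.
    The selected case maximizes the number of modules stable in more than
    half of the cases (ties -> smaller deep_split, then larger minimum
    module size).  Returns the winning partition and the full stability
    table.
    """
    if grid is None:
        grid = default_tree_cut_grid()
    if not grid:
        raise ConfigurationError("tree-cut grid must be non-empty")
    d = _validate_dissimilarity(dissimilarity)
    link = average_linkage(d)
    partitions = [_cut_from_linkage(link, d, genes, p) for p in grid]
    member_sets = [
        {m: set(part.members(m)) for m in part.module_labels()}
        for part in partitions
    ]
    n_cases = len(grid)
    rows = []
    stable_counts = []
    for ci, (params, part) in enumerate(zip(grid, partitions)):
        n_stable = 0
        for m, mset in member_sets[ci].items():
            support = sum(
                1
                for other in member_sets
                if any(_jaccard(mset, oset) >= 0.5 for oset in other.values())
            )
            stability = support / n_cases
            stable = stability > 0.5
            n_stable += stable
            rows.append(
                {
                    "case": ci,
                    "min_module_size": params.min_module_size,
                    "deep_split": params.deep_split,
                    "max_dissimilarity": params.max_dissimilarity,
                    "module": m,
                    "size": len(mset),
                    "stability": stability,
                    "stable": stable,
                }
            )
        stable_counts.append(n_stable)
    best = min(
        range(n_cases),
        key=lambda ci: (
            -stable_counts[ci],
            grid[ci].deep_split,
            -grid[ci].min_module_size,
            ci,
        ),
    )
    table = pd.DataFrame(
        rows,
        columns=[
            "case",
            "min_module_size",
            "deep_split",
            "max_dissimilarity",
            "module",
            "size",
            "stability",
            "stable",
        ],
    )
    table["selected_case"] = table["case"] == best
    return partitions[best], table
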