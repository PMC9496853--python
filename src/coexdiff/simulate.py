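"""Synthetic two-dataset expression studies with planted network signal.

The generator emulates the statistical structure a blood-transcriptome
co-expression study assumes: correlated gene modules, modules whose
intra-module correlation changes with disease (gain/loss of connectivity),
modules with mean expression shifts, designated differential-hub genes, and
dataset-level batch effects of the additive + multiplicative kind.

Each module is an equicorrelated block built from one latent factor per
condition: ``x = sqrt(rho) * f + sqrt(1 - rho) * eps`` so every within-module
gene pair has population correlation ``rho``.  Hub genes get their factor
loading raised (to ``hub_loading``) in the disease condition only, which
creates the disease-specific excess of extreme-similarity edges the
edge-count analysis detects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    CONTROL,
    DISEASE,
    ConfigurationError,
    ExpressionDataset,
    ModulePartition,
    color_labels,
)


@dataclass
class SimulationConfig:
    """Parameters of a planted-signal two-dataset study.

    ``samples_per_condition`` maps each dataset id to a
    ``(n_disease, n_control)`` pair.  Correlations are population values of
    the equicorrelated block model.  ``de_shift`` is a log2 mean shift added
    to disease samples of the designated DE modules.  ``batch_gamma`` is the
    SD of per-gene additive batch offsets and ``batch_delta`` the SD of
    per-gene log variance factors; both apply to every non-reference dataset
    (the first dataset id is the reference batch).
    """

    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (100, 100, 100, 100)
    samples_per_condition: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"ds1": (50, 50), "ds2": (50, 50)}
    )
    base_corr: float = 0.6
    dcoe_corr: float = 0.6
    dcoe_module_ids: tuple[int, ...] = ()
    de_shift: float = 0.0
    de_module_ids: tuple[int, ...] = ()
    hub_genes_per_module: int = 0
    hub_module_ids: tuple[int, ...] | None = None
    hub_loading: float = 0.9
    batch_gamma: float = 0.0
    batch_delta: float = 0.0
    noise_sd: float = 1.0
    gene_scale_sd: float = 0.3
    baseline_mean: float = 7.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                "module_sizes sum exceeds n_genes"
            )
        for name in ("base_corr", "dcoe_corr"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if not 0.0 <= self.hub_loading < 1.0:
            raise ConfigurationError("hub_loading must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if self.gene_scale_sd < 0:
            raise ConfigurationError("gene_scale_sd must be non-negative")
        if self.batch_gamma < 0 or self.batch_delta < 0:
            raise ConfigurationError("batch scales must be non-negative")
        n_mod = len(self.module_sizes)
        for name in ("dcoe_module_ids", "de_module_ids"):
            ids = getattr(self, name)
            if any(i < 0 or i >= n_mod for i in ids):
                raise ConfigurationError(f"{name} out of range 0..{n_mod - 1}")
        if self.hub_module_ids is not None and any(
            i < 0 or i >= n_mod for i in self.hub_module_ids
        ):
            raise ConfigurationError(f"hub_module_ids out of range 0..{n_mod - 1}")
        if self.hub_genes_per_module < 0:
            raise ConfigurationError("hub_genes_per_module must be >= 0")
        for ds, (nd, nc) in self.samples_per_condition.items():
            if nd < 1 or nc < 1:
                raise ConfigurationError(
                    f"samples_per_condition[{ds!r}] must be >= 1 per condition"
                )


@dataclass
class SimulatedStudy:
    """Generated datasets plus the planted ground truth."""

    datasets: list[ExpressionDataset]
    truth_modules: ModulePartition
    truth_dcoe: list[str]
    truth_de: list[tuple[str, int]]  # (module label, shift sign)
    truth_hubs: list[str]
    config: SimulationConfig


def _module_gene_groups(config: SimulationConfig) -> tuple[list[str], list[list[str]]]:
    width = max(4, len(str(config.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(1, config.n_genes + 1)]
    groups, start = [], 0
    for size in config.module_sizes:
        groups.append(genes[start : start + size])
        start += size
    return genes, groups


def generate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate a reproducible multi-dataset study with planted signal.

    The same ``config`` (including its seed) always produces bitwise
    identical matrices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes, groups = _module_gene_groups(config)
    partition = color_labels(groups, genes)
    hub_mods = (
        tuple(config.hub_module_ids)
        if config.hub_module_ids is not None
        else tuple(config.dcoe_module_ids)
    )

    # Gene-level quantities shared across datasets/conditions.  Gene-wise
    # expression scales are log-normal so the SD filter ranks genes
    # consistently across datasets, as it does on real transcriptomes.
    baseline = config.baseline_mean + rng.normal(0.0, 1.0, size=config.n_genes)
    gene_scale = np.exp(rng.normal(0.0, config.gene_scale_sd, size=config.n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    truth_hubs: list[str] = []
    hub_index: set[int] = set()
    for mi in hub_mods:
        chosen = groups[mi][: config.hub_genes_per_module]
        truth_hubs.extend(chosen)
        hub_index.update(gene_pos[g] for g in chosen)

    dataset_ids = list(config.samples_per_condition)
    datasets: list[ExpressionDataset] = []
    for di, ds_id in enumerate(dataset_ids):
        n_dis, n_con = config.samples_per_condition[ds_id]
        blocks = []
        for cond, n in ((DISEASE, n_dis), (CONTROL, n_con)):
            x = rng.normal(0.0, 1.0, size=(config.n_genes, n))
            for mi, members in enumerate(groups):
                rho = (
                    config.dcoe_corr
                    if cond == DISEASE and mi in config.dcoe_module_ids
                    else config.base_corr
                )
                lam = np.full(len(members), np.sqrt(rho))
                if cond == DISEASE and mi in hub_mods:
                    for j, g in enumerate(members):
                        if gene_pos[g] in hub_index:
                            lam[j] = config.hub_loading
                f = rng.normal(0.0, 1.0, size=n)
                rows = [gene_pos[g] for g in members]
                x[rows, :] = (
                    lam[:, None] * f[None, :]
                    + np.sqrt(1.0 - lam**2)[:, None] * x[rows, :]
                )
            x = config.noise_sd * gene_scale[:, None] * x + baseline[:, None]
            if cond == DISEASE and config.de_shift != 0.0:
                for mi in config.de_module_ids:
                    rows = [gene_pos[g] for g in groups[mi]]
                    x[rows, :] += config.de_shift
            blocks.append((cond, x))

        # Batch effect: every dataset after the first gets per-gene additive
        # offsets and multiplicative variance factors (ComBat model family).
        gamma = rng.normal(0.0, 1.0, size=config.n_genes)
        logdelta = rng.normal(0.0, 1.0, size=config.n_genes)
        if di > 0 and (config.batch_gamma > 0 or config.batch_delta > 0):
            offset = config.batch_gamma * gamma
            scale = np.exp(config.batch_delta * logdelta)
            new_blocks = []
            for cond, x in blocks:
                center = x.mean(axis=1, keepdims=True)
                new_blocks.append(
                    (cond, (x - center) * scale[:, None] + center + offset[:, None])
                )
            blocks = new_blocks

        mats, conds, names = [], [], []
        for cond, x in blocks:
            mats.append(x)
            for j in range(x.shape[1]):
                names.append(f"{ds_id}_{cond[:3]}{j + 1:03d}")
                conds.append(cond)
        values = pd.DataFrame(np.hstack(mats), index=genes, columns=names)
        datasets.append(
            ExpressionDataset(
                values,
                condition=pd.Series(conds, index=names),
                batch=pd.Series(ds_id, index=names),
            )
        )

    label_of = {mi: partition.labels[groups[mi][0]] for mi in range(len(groups))}
    return SimulatedStudy(
        datasets=datasets,
        truth_modules=partition,
        truth_dcoe=[label_of[mi] for mi in config.dcoe_module_ids],
        truth_de=[
            (label_of[mi], int(np.sign(config.de_shift)))
            for mi in config.de_module_ids
        ],
        truth_hubs=truth_hubs,
        config=config,
    )
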