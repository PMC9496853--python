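"""Core in-memory containers shared across the pipeline.

Expression data travel as a genes x samples :class:`pandas.DataFrame` of
log2-scale values together with per-sample condition ("disease"/"control")
and batch (dataset id) annotations.  Module memberships are a gene -> color
label map where the reserved label ``"grey"`` means "unassigned".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DISEASE = "disease"
CONTROL = "control"
UNASSIGNED = "grey"

#: WGCNA-style module color sequence, assigned by decreasing module size.
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


class ValidationError(ValueError):
    """Raised when input data violate a documented precondition."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is outside its valid range."""


@dataclass
class ExpressionDataset:
    """A genes x samples expression matrix with sample annotations.

    Parameters
    ----------
    values
        Log2-scale expression, genes as rows, samples as columns.
    condition
        Per-sample label, ``"disease"`` or ``"control"``; indexed by sample id.
    batch
        Per-sample dataset/batch id; indexed by sample id.
    """

    values: pd.DataFrame
    condition: pd.Series
    batch: pd.Series

    def __post_init__(self) -> None:
        self.condition = pd.Series(self.condition)
        self.batch = pd.Series(self.batch)
        self.validate()

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValidationError("expression matrix contains missing values")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {list(dups)[:5]}")
        for name, ann in (("condition", self.condition), ("batch", self.batch)):
            if not ann.index.equals(self.values.columns):
                if set(ann.index) == set(self.values.columns):
                    # reorder silently; order mismatches are common after IO
                    setattr(self, name, ann.loc[self.values.columns])
                else:
                    raise ValidationError(
                        f"{name} annotation does not cover the sample columns"
                    )
        bad = set(self.condition.unique()) - {DISEASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown condition labels: {sorted(bad)}")

    # -- convenience accessors -------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[list(genes)], self.condition, self.batch
        )

    def subset_condition(self, label: str) -> "ExpressionDataset":
        keep = self.condition.index[self.condition == label]
        return ExpressionDataset(
            self.values[keep], self.condition[keep], self.batch[keep]
        )


@dataclass
class ModulePartition:
    """Gene -> module-label assignment; ``"grey"`` marks unassigned genes."""

    labels: pd.Series

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=object)

    @property
    def genes(self) -> list[str]:
        return list(self.labels.index)

    def module_labels(self) -> list[str]:
        """Non-grey labels, largest module first (ties by label)."""
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        return sorted(sizes.index, key=lambda m: (-sizes[m], m))

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def sizes(self) -> dict[str, int]:
        return {m: len(self.members(m)) for m in self.module_labels()}

    def n_unassigned(self) -> int:
        return int((self.labels == UNASSIGNED).sum())


def color_labels(groups: list[list[str]], universe: list[str]) -> ModulePartition:
    """Assign color labels to gene groups by decreasing size; rest is grey.

    Size ties are broken by the position of each group's first gene in the
    universe so labelling is deterministic.
    """
    pos = {g: i for i, g in enumerate(universe)}
    order = sorted(
        range(len(groups)),
        key=lambda i: (-len(groups[i]), min(pos[g] for g in groups[i])),
    )
    labels = pd.Series(UNASSIGNED, index=list(universe), dtype=object)
    for rank, gi in enumerate(order):
        name = (
            MODULE_COLORS[rank]
            if rank < len(MODULE_COLORS)
            else f"module{rank + 1}"
        )
        labels.loc[groups[gi]] = name
    return ModulePartition(labels)
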