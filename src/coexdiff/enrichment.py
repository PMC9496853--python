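"""Hypergeometric gene-set enrichment against GMT collections.

For a candidate gene set of size c, a pathway of size p and a background
universe of N genes, the enrichment p-value is the upper tail

    P = sum_{k=i}^{min(c,p)} C(c,k) C(N-c, p-k) / C(N,p)

where i is the observed overlap.  Pathway members outside the background
are dropped before testing, and BH correction is applied across pathways.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .containers import ValidationError
from .diffexpr import bh_adjust


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe they are tested against."""

    sets: dict[str, list[str]]
    universe: list[str]

    def __post_init__(self) -> None:
        self.sets = {name: list(dict.fromkeys(g)) for name, g in self.sets.items()}
        self.universe = list(dict.fromkeys(self.universe))

    @property
    def n_background(self) -> int:
        return len(self.universe)


def hypergeom_pvalue(N: int, p: int, c: int, i: int) -> float:
    """Upper-tail hypergeometric p-value (computed in log space by scipy).

    N: background size; p: pathway size; c: candidate-set size; i: overlap.
    """
    if not (0 <= i <= min(c, p)):
        raise ValidationError("overlap i must satisfy 0 <= i <= min(c, p)")
    if p > N or c > N:
        raise ValidationError("set sizes cannot exceed the background size")
    # draws of size p from N with c "successes"; P[X >= i]
    return float(hypergeom.sf(i - 1, N, c, p))


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = list(dict.fromkeys(g for g in parts[2:] if g))
    return sets


def write_gmt(path, sets: dict[str, list[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def enrich(candidates: list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric enrichment of a candidate set against every pathway.

    Returns a table with overlap counts, raw and BH-adjusted p-values and a
    significance flag at adjusted p < 0.05, sorted by raw p.
    """
    if not candidates:
        raise ValidationError("candidate gene list is empty")
    universe = set(collection.universe)
    cand = list(dict.fromkeys(candidates))
    outside = [g for g in cand if g not in universe]
    if outside:
        warnings.warn(
            f"{len(outside)} candidate genes outside the background dropped",
            stacklevel=2,
        )
        cand = [g for g in cand if g in universe]
    if not cand:
        raise ValidationError("no candidate genes remain inside the background")
    cand_set = set(cand)
    N, c = len(universe), len(cand_set)
    rows = []
    for name, genes in collection.sets.items():
        members = [g for g in genes if g in universe]
        p_size = len(members)
        overlap = len(cand_set.intersection(members))
        pval = hypergeom_pvalue(N, p_size, c, overlap) if p_size else 1.0
        rows.append(
            {
                "pathway": name,
                "pathway_size": p_size,
                "candidate_size": c,
                "overlap": overlap,
                "p": pval,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < 0.05
    return table.sort_values(["p", "pathway"], kind="mergesort").reset_index(
        drop=True
    )
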