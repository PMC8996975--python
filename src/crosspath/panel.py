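"""Cross-cohort gene panel construction.

A gene that sits in the leading edge of many significantly enriched sets
within one cohort is a recurrent driver of that cohort's expression
shift.  Counting those leading-edge memberships (the *frequency* score),
attaching a linear-scale fold change with an up/down call, and
intersecting the resulting per-cohort candidate lists yields the shared
biomarker panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix
from .gsea import EnrichmentResult

__all__ = [
    "FrequencyTable",
    "FoldChangeRecord",
    "leading_edge_frequency",
    "select_high_frequency_genes",
    "fold_change",
    "classify_deg",
    "intersect_panels",
    "intersect_pathways",
]


@dataclass
class FrequencyTable:
    """gene → number of significant leading edges containing it."""

    counts: dict[str, int]
    total_sets: int

    def __post_init__(self) -> None:
        for g, c in self.counts.items():
            if not (0 <= c <= self.total_sets):
                raise ValueError(f"count {c} for {g!r} outside [0, {self.total_sets}]")

    def ordered(self) -> list[tuple[str, int]]:
        """(gene, count) pairs ordered by count descending, symbol ascending."""
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))

    def to_series(self) -> pd.Series:
        items = self.ordered()
        return pd.Series([c for _, c in items], index=[g for g, _ in items], name="frequency")


@dataclass
class FoldChangeRecord:
    gene_symbol: str
    fc: float
    call: str  # up | down | neither
    usable: bool = True


def leading_edge_frequency(significant: list[EnrichmentResult]) -> FrequencyTable:
    """Count, per gene, the significant sets whose leading edge contains it."""
    counts: dict[str, int] = {}
    for res in significant:
        for gene in set(res.leading_edge):
            counts[gene] = counts.get(gene, 0) + 1
    return FrequencyTable(counts, total_sets=len(significant))


def select_high_frequency_genes(
    table: FrequencyTable,
    top_k: int | None = None,
    min_count: int | None = None,
) -> list[str]:
    """Pick the recurrently enriched genes.

    Exactly one of ``top_k`` (k highest counts, ties at the boundary
    kept) or ``min_count`` (all genes with count >= threshold) must be
    given.  Returns symbols ordered (count desc, symbol asc).
    """
    if (top_k is None) == (min_count is None):
        raise ValueError("supply exactly one of top_k or min_count")
    ordered = table.ordered()
    if not ordered:
        return []
    if min_count is not None:
        return [g for g, c in ordered if c >= min_count]
    if top_k >= len(ordered):
        return [g for g, _ in ordered]
    boundary = ordered[top_k - 1][1]
    return [g for g, c in ordered if c >= boundary]


def fold_change(linear: ExpressionMatrix, genes: list[str]) -> list[FoldChangeRecord]:
    """Disease/control ratio of linear-scale means for each gene.

    Genes whose control mean is zero are flagged unusable rather than
    raising (cannot happen for strictly positive linear matrices, but
    callers may pass pre-aggregated data).
    """
    if linear.scale != "linear":
        raise ValueError("fold change requires the linear-scale matrix")
    missing = [g for g in genes if g not in linear.row_ids]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    dis, ctl = linear.classes
    sub = linear.subset_rows(genes)
    mu_d = sub.class_matrix(dis).mean(axis=1)
    mu_c = sub.class_matrix(ctl).mean(axis=1)
    records = []
    for g, md, mc in zip(genes, mu_d, mu_c):
        if mc == 0:
            records.append(FoldChangeRecord(g, np.nan, "neither", usable=False))
        else:
            records.append(FoldChangeRecord(g, float(md / mc), "neither"))
    return records


def classify_deg(fc: float, up_cut: float, down_cut: float) -> str:
    """Strict-comparison call: ``up`` if fc > up_cut, ``down`` if
    fc < down_cut, else ``neither``."""
    if not (0 < down_cut < up_cut):
        raise ValueError("require 0 < down_cut < up_cut")
    if not np.isfinite(fc) or fc <= 0:
        return "neither"
    if fc > up_cut:
        return "up"
    if fc < down_cut:
        return "down"
    return "neither"


@dataclass
class VennCounts:
    only_a: int
    only_b: int
    both: int

    def as_dict(self) -> dict[str, int]:
        return {"only_a": self.only_a, "only_b": self.only_b, "both": self.both}


def intersect_panels(genes_a, genes_b) -> tuple[list[str], VennCounts]:
    """Exact symbol intersection of two per-cohort gene lists, ordered by
    symbol, with Venn counts (only-A, only-B, both)."""
    a, b = set(genes_a), set(genes_b)
    both = sorted(a & b)
    return both, VennCounts(len(a - b), len(b - a), len(both))


def _canon(name: str) -> str:
    return " ".join(name.split()).casefold()


def intersect_pathways(sets_a, sets_b) -> tuple[list[str], VennCounts]:
    """Case-insensitive, whitespace-normalized intersection of pathway
    names; the returned names use cohort A's stylization."""
    canon_a = {_canon(n): n for n in sets_a}
    canon_b = {_canon(n) for n in sets_b}
    both_keys = sorted(set(canon_a) & canon_b)
    both = [canon_a[k] for k in both_keys]
    only_a = len(set(canon_a) - canon_b)
    only_b = len(canon_b - set(canon_a))
    return both, VennCounts(only_a, only_b, len(both))
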