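"""End-to-end orchestration: filter → collapse → absolute GSEA →
significant sets → leading-edge frequency → fold change → cross-cohort
intersection, with stage-count bookkeeping for the run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .containers import ExpressionMatrix, GeneSetCollection, ProbeAnnotation
from .gsea import EnrichmentResult, GseaConfig, permutation_statistics, significant_sets
from .panel import (
    FrequencyTable,
    VennCounts,
    classify_deg,
    fold_change,
    intersect_panels,
    intersect_pathways,
    leading_edge_frequency,
    select_high_frequency_genes,
)
from .preprocess import FilterConfig, collapse_to_genes, nonspecific_filter

__all__ = ["CohortConfig", "PanelSelection", "CohortResult", "PipelineReport",
           "run_cohort", "run_two_cohorts", "config_hash"]


@dataclass
class PanelSelection:
    """How the recurrent leading-edge genes are picked: exactly one of
    top_k (ties at the boundary kept) or min_count."""

    top_k: int | None = 10
    min_count: int | None = None

    def __post_init__(self) -> None:
        if (self.top_k is None) == (self.min_count is None):
            raise ValueError("set exactly one of top_k or min_count")


@dataclass
class CohortConfig:
    filter: FilterConfig = field(default_factory=FilterConfig)
    gsea: GseaConfig = field(default_factory=GseaConfig)
    up_cut: float = 1.0
    down_cut: float = 0.75
    selection: PanelSelection = field(default_factory=PanelSelection)


@dataclass
class CohortResult:
    passing_probes: list[str]
    chosen_probe: dict[str, str]
    gene_log2: ExpressionMatrix
    gene_linear: ExpressionMatrix
    enrichment: list[EnrichmentResult]
    significant: list[EnrichmentResult]
    frequency: FrequencyTable
    selected_genes: list[str]
    up_genes: list[str]
    down_genes: list[str]
    counts: dict[str, int]


@dataclass
class PipelineReport:
    cohort_a: CohortResult
    cohort_b: CohortResult
    panel_up: list[str]
    panel_down: list[str]
    panel: list[str]
    gene_venn: VennCounts
    pathway_common: list[str]
    pathway_venn: VennCounts
    config_hash: str
    counts: dict[str, int]


def config_hash(*configs) -> str:
    """Stable digest of the semantic configuration fields."""
    payload = json.dumps([dataclasses.asdict(c) for c in configs], sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_cohort(
    linear: ExpressionMatrix,
    log2m: ExpressionMatrix,
    annot: ProbeAnnotation,
    collection: GeneSetCollection,
    cfg: CohortConfig | None = None,
) -> CohortResult:
    """Single-cohort pipeline from probe matrices to the candidate gene list."""
    cfg = cfg or CohortConfig()
    passing = nonspecific_filter(linear, log2m, cfg.filter)
    if not passing:
        raise RuntimeError("stage nonspecific_filter: no probes passed")

    gene_log2, chosen = collapse_to_genes(log2m.subset_rows(passing), annot)
    # the linear matrix is collapsed with the SAME chosen probes so fold
    # changes describe exactly the rows that were ranked
    genes = list(gene_log2.row_ids)
    lin_rows = linear.values.loc[[chosen[g] for g in genes]].copy()
    lin_rows.index = gene_log2.values.index.copy()
    gene_linear = ExpressionMatrix(lin_rows, "linear", linear.phenotype, linear.classes)

    enrichment = permutation_statistics(gene_log2, collection, cfg.gsea)
    sig = significant_sets(enrichment, cfg.gsea)
    freq = leading_edge_frequency(sig)
    selected = select_high_frequency_genes(
        freq, top_k=cfg.selection.top_k, min_count=cfg.selection.min_count
    ) if freq.counts else []

    up_genes, down_genes = [], []
    if selected:
        for rec in fold_change(gene_linear, selected):
            if not rec.usable:
                continue
            rec.call = classify_deg(rec.fc, cfg.up_cut, cfg.down_cut)
            if rec.call == "up":
                up_genes.append(rec.gene_symbol)
            elif rec.call == "down":
                down_genes.append(rec.gene_symbol)

    counts = {
        "probes_in": len(linear.row_ids),
        "probes_passing": len(passing),
        "genes_after_collapse": len(genes),
        "sets_tested": len(enrichment),
        "sets_significant": len(sig),
        "genes_selected": len(selected),
        "genes_up": len(up_genes),
        "genes_down": len(down_genes),
    }
    return CohortResult(passing, chosen, gene_log2, gene_linear, enrichment, sig,
                        freq, selected, sorted(up_genes), sorted(down_genes), counts)


def run_two_cohorts(
    inputs_a: tuple[ExpressionMatrix, ExpressionMatrix, ProbeAnnotation, GeneSetCollection],
    inputs_b: tuple[ExpressionMatrix, ExpressionMatrix, ProbeAnnotation, GeneSetCollection],
    cfg_a: CohortConfig | None = None,
    cfg_b: CohortConfig | None = None,
) -> PipelineReport:
    """Dual-cohort pipeline: run each cohort, then intersect the up/down
    candidate lists (direction must agree) and the significant pathways."""
    cfg_a = cfg_a or CohortConfig()
    cfg_b = cfg_b or CohortConfig()
    res_a = run_cohort(*inputs_a, cfg_a)
    res_b = run_cohort(*inputs_b, cfg_b)

    panel_up, venn_up = intersect_panels(res_a.up_genes, res_b.up_genes)
    panel_down, venn_down = intersect_panels(res_a.down_genes, res_b.down_genes)
    panel = sorted(set(panel_up) | set(panel_down))
    all_a = set(res_a.up_genes) | set(res_a.down_genes)
    all_b = set(res_b.up_genes) | set(res_b.down_genes)
    gene_venn = VennCounts(
        len(all_a - set(panel)), len(all_b - set(panel)), len(panel)
    )
    path_common, path_venn = intersect_pathways(
        [r.set_name for r in res_a.significant], [r.set_name for r in res_b.significant]
    )
    counts = {
        **{f"a_{k}": v for k, v in res_a.counts.items()},
        **{f"b_{k}": v for k, v in res_b.counts.items()},
        "panel_up": len(panel_up),
        "panel_down": len(panel_down),
        "panel_size": len(panel),
        "pathways_common": len(path_common),
    }
    return PipelineReport(
        res_a, res_b, panel_up, panel_down, panel, gene_venn,
        path_common, path_venn, config_hash(cfg_a, cfg_b), counts,
    )
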