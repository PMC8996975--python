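"""Nonspecific probe filtering and probe-to-gene collapse.

Microarray probes that never rise above background, or that barely vary
across subjects, carry no ranking information and inflate the multiple
testing burden.  The filter here combines two views of the same RNA:

* an intensity floor on the **linear** track — mean linear intensity
  across all samples must reach ``intensity_floor`` (default 50);
* a variability window on the **log2** track — the coefficient of
  variation (100 · sd/mean, sample sd with n−1) must fall inside the
  closed interval ``[cv_low, cv_high]`` (default [10, 100] percent).

Probes passing both predicates are intersected.  Surviving probes are
then collapsed to genes by keeping, per gene, the single probe with the
highest mean expression across all samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeAnnotation

__all__ = ["FilterConfig", "compute_cv", "nonspecific_filter", "collapse_to_genes"]


@dataclass
class FilterConfig:
    """Thresholds of the dual-track nonspecific filter.

    ``strict_floor=True`` requires *every* sample (not the mean) to reach
    the intensity floor.
    """

    intensity_floor: float = 50.0
    cv_low: float = 10.0
    cv_high: float = 100.0
    strict_floor: bool = False

    def __post_init__(self) -> None:
        if self.intensity_floor < 0:
            raise ValueError("intensity_floor must be >= 0")
        if not (0 <= self.cv_low < self.cv_high):
            raise ValueError("require 0 <= cv_low < cv_high")


def compute_cv(matrix: ExpressionMatrix) -> pd.Series:
    """Per-row coefficient of variation in percent: 100 · sd / mean.

    Sample standard deviation (n−1 denominator), pooled across all
    samples of both classes.  Rows with zero mean get NaN (they can
    never pass a CV window) rather than raising.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("CV requires at least 2 samples")
    vals = matrix.values.to_numpy(dtype=float)
    mean = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    return pd.Series(cv, index=matrix.row_ids, name="cv_pct")


def nonspecific_filter(
    linear: ExpressionMatrix, log2m: ExpressionMatrix, cfg: FilterConfig | None = None
) -> list[str]:
    """Probe ids passing the intensity floor (linear track) AND the CV
    window (log2 track), in the input row order.

    The two matrices must describe the same probes and samples; a
    mismatch raises with the symmetric difference of the probe sets.
    """
    cfg = cfg or FilterConfig()
    if set(linear.row_ids) != set(log2m.row_ids):
        diff = sorted(set(linear.row_ids) ^ set(log2m.row_ids))
        raise ValueError(f"probe sets differ between tracks; symmetric difference: {diff[:10]}"
                         + ("..." if len(diff) > 10 else ""))
    if set(linear.sample_ids) != set(log2m.sample_ids):
        raise ValueError("sample sets differ between the two normalization tracks")
    log2_aligned = log2m.subset_rows(linear.row_ids)

    lin_vals = linear.values.to_numpy(dtype=float)
    if cfg.strict_floor:
        floor_ok = (lin_vals >= cfg.intensity_floor).all(axis=1)
    else:
        floor_ok = lin_vals.mean(axis=1) >= cfg.intensity_floor

    cv = compute_cv(log2_aligned).to_numpy()
    cv_ok = (cv >= cfg.cv_low) & (cv <= cfg.cv_high)  # NaN CV fails both

    passing = linear.row_ids[floor_ok & cv_ok]
    return list(dict.fromkeys(passing))


def collapse_to_genes(
    matrix: ExpressionMatrix, annot: ProbeAnnotation
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Collapse a probe-level matrix to gene level.

    Unmapped probes are dropped.  For each gene the probe with the
    highest mean expression across all samples is selected and its full
    row becomes the gene's row; ties on the mean go to the
    lexicographically smallest probe id.  Returns the gene-level matrix
    and the gene → chosen-probe map.
    """
    means = matrix.values.mean(axis=1)
    best: dict[str, tuple[float, str]] = {}
    for probe in matrix.row_ids:
        gene = annot.gene_of(probe)
        if gene is None:
            continue
        m = float(means.loc[probe])
        cur = best.get(gene)
        if cur is None or m > cur[0] or (m == cur[0] and probe < cur[1]):
            best[gene] = (m, probe)
    if not best:
        raise ValueError("no mapped probes to collapse")
    genes = sorted(best)
    chosen = {g: best[g][1] for g in genes}
    gene_values = matrix.values.loc[[chosen[g] for g in genes]].copy()
    gene_values.index = pd.Index(genes, name="gene_symbol")
    collapsed = ExpressionMatrix(gene_values, matrix.scale, matrix.phenotype, matrix.classes)
    return collapsed, chosen
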