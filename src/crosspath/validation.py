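"""Wet-lab validation arithmetic: relative qPCR quantification and
nonparametric group comparison.

The 2^-ddCt method: each sample's target-gene Ct is normalized against a
reference (housekeeping) gene measured in the same sample (dCt), then
against the mean dCt of a calibrator group (ddCt).  One PCR cycle is one
doubling, so relative quantity rq = 2^-ddCt and log2 fold expression is
exactly -ddCt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QpcrMeasurement",
    "RelativeExpression",
    "aggregate_replicates",
    "relative_expression",
    "mann_whitney",
]

CT_RANGE = (0.0, 45.0)
REPLICATE_TOLERANCE_CYCLES = 1.0  # replicates farther than this from the
# replicate median are treated as pipetting outliers and discarded


@dataclass
class QpcrMeasurement:
    sample_id: str
    group: str
    gene: str
    ct_gene: tuple[float, ...]
    ct_ref: tuple[float, ...]

    def __post_init__(self) -> None:
        for ct in (*self.ct_gene, *self.ct_ref):
            if not (CT_RANGE[0] < ct < CT_RANGE[1]):
                raise ValueError(f"Ct {ct} outside plausible range {CT_RANGE}")


@dataclass
class RelativeExpression:
    sample_id: str
    group: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    rq: float
    log2_rq: float


def aggregate_replicates(cts) -> float | None:
    """Mean Ct after dropping replicates > 1 cycle from the replicate
    median; None when fewer than 2 usable replicates remain."""
    arr = np.asarray(cts, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        return None
    keep = arr[np.abs(arr - np.median(arr)) <= REPLICATE_TOLERANCE_CYCLES]
    if keep.size < 2:
        return None
    return float(keep.mean())


def relative_expression(
    measurements: list[QpcrMeasurement], calibrator_group: str
) -> list[RelativeExpression]:
    """Per-sample 2^-ddCt relative to the mean dCt of the calibrator group.

    Samples whose gene or reference triplicate collapses below two usable
    replicates are excluded.  The calibrator group must contain at least
    one usable sample for every gene present.
    """
    usable: list[tuple[QpcrMeasurement, float]] = []
    for m in measurements:
        ct_g = aggregate_replicates(m.ct_gene)
        ct_r = aggregate_replicates(m.ct_ref)
        if ct_g is None or ct_r is None:
            continue
        usable.append((m, ct_g - ct_r))

    calib: dict[str, list[float]] = {}
    for m, dct in usable:
        if m.group == calibrator_group:
            calib.setdefault(m.gene, []).append(dct)
    genes = {m.gene for m, _ in usable}
    missing = sorted(g for g in genes if g not in calib)
    if missing:
        raise ValueError(f"calibrator group {calibrator_group!r} empty for genes {missing}")
    calib_mean = {g: float(np.mean(v)) for g, v in calib.items()}

    out = []
    for m, dct in usable:
        ddct = dct - calib_mean[m.gene]
        out.append(
            RelativeExpression(
                m.sample_id, m.group, m.gene,
                delta_ct=dct, delta_delta_ct=ddct,
                rq=float(2.0 ** (-ddct)), log2_rq=-ddct,
            )
        )
    return out


def relative_expression_frame(results: list[RelativeExpression]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in results],
            "group": [r.group for r in results],
            "gene": [r.gene for r in results],
            "delta_ct": [r.delta_ct for r in results],
            "delta_delta_ct": [r.delta_delta_ct for r in results],
            "rq": [r.rq for r in results],
            "log2_rq": [r.log2_rq for r in results],
        }
    )


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration p when the combined sample is small (n <= 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  Returns (U of group_a, two-sided p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    combined = np.concatenate([a, b])
    no_ties = len(np.unique(combined)) == combined.size
    if a.size + b.size <= 12 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(1.0, res.pvalue))
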