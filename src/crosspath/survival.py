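"""Expression-split survival analysis: Kaplan–Meier curves, the log-rank
test, and an O/E hazard-ratio estimate.

Subjects are divided into high- and low-expression groups (median split
by default — deliberately not an optimized cutoff, which would inflate
significance), survival in each group is summarized with the
product-limit estimator, and the groups are compared with the standard
log-rank statistic.  The hazard ratio is estimated from the
observed/expected event counts, HR = (O_h/E_h)/(O_l/E_l), with a
log-scale 95% CI using variance 1/E_h + 1/E_l.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalRecord",
    "KmCurve",
    "LogrankResult",
    "split_by_expression",
    "km_estimate",
    "logrank_hr",
]


@dataclass
class SurvivalRecord:
    subject_id: str
    time: float
    event: int  # 1 = death observed, 0 = censored
    expression_value: float

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("follow-up time must be >= 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


@dataclass
class KmCurve:
    """Product-limit estimate: S(t) drops only at event times."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray
    deaths: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogrankResult:
    chi2: float
    p: float
    hr: float
    ci95: tuple[float, float]
    observed: tuple[float, float]  # (high, low)
    expected: tuple[float, float]
    hr_unbounded: bool = False


def split_by_expression(
    records: list[SurvivalRecord], rule: str = "median", cutoff: float | None = None
) -> tuple[list[SurvivalRecord], list[SurvivalRecord]]:
    """(high, low) groups by marker level.

    Median rule: high = strictly above the sample median (ties at the
    median go low).  Cutoff rule: high = strictly above the supplied
    threshold.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    values = np.array([r.expression_value for r in records])
    if np.all(values == values[0]):
        raise ValueError("all expression values identical; cannot split")
    if rule == "median":
        threshold = float(np.median(values))
    elif rule == "cutoff":
        if cutoff is None:
            raise ValueError("cutoff rule requires a threshold")
        threshold = cutoff
    else:
        raise ValueError(f"unknown split rule {rule!r}")
    high = [r for r in records if r.expression_value > threshold]
    low = [r for r in records if r.expression_value <= threshold]
    if not high or not low:
        raise ValueError("split produced an empty group")
    return high, low


def km_estimate(records: list[SurvivalRecord]) -> KmCurve:
    """Kaplan–Meier product-limit curve for one group.

    At each distinct event time t_i with d_i deaths among n_i at risk,
    S multiplies by (1 - d_i/n_i).  Subjects censored at t leave the
    risk set after t (events precede censorings at ties).
    """
    if not records:
        raise ValueError("empty group")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events == 1])
    at_risk, deaths, surv = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int((times >= t).sum())  # censored exactly at t still at risk
        d_i = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d_i / n_i
        at_risk.append(n_i)
        deaths.append(d_i)
        surv.append(s)
    return KmCurve(
        times=event_times.astype(float),
        at_risk=np.array(at_risk, dtype=int),
        deaths=np.array(deaths, dtype=int),
        survival=np.array(surv, dtype=float),
    )


def logrank_hr(high: list[SurvivalRecord], low: list[SurvivalRecord]) -> LogrankResult:
    """Log-rank comparison of the two expression groups.

    At each distinct event time the observed deaths in the high group
    are compared with the hypergeometric expectation given the risk
    sets; chi2 = (O_h - E_h)^2 / V with 1 df.
    """
    if not high or not low:
        raise ValueError("both groups must be nonempty")
    t_h = np.array([r.time for r in high]); e_h = np.array([r.event for r in high])
    t_l = np.array([r.time for r in low]); e_l = np.array([r.event for r in low])
    all_t = np.concatenate([t_h, t_l]); all_e = np.concatenate([e_h, e_l])
    if all_e.sum() == 0:
        raise ValueError("no events in either group")

    o_high = o_low = exp_high = exp_low = var = 0.0
    for t in np.unique(all_t[all_e == 1]):
        n1 = float((t_h >= t).sum())
        n2 = float((t_l >= t).sum())
        n = n1 + n2
        d1 = float(((t_h == t) & (e_h == 1)).sum())
        d2 = float(((t_l == t) & (e_l == 1)).sum())
        d = d1 + d2
        if n == 0:
            continue
        o_high += d1
        o_low += d2
        exp_high += d * n1 / n
        exp_low += d * n2 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)

    chi2 = (o_high - exp_high) ** 2 / var if var > 0 else 0.0
    p = float(stats.chi2.sf(chi2, df=1))

    unbounded = o_high == 0 or o_low == 0
    if unbounded:
        hr = math.inf if o_low == 0 else 0.0
        ci = (math.nan, math.nan)
    else:
        hr = (o_high / exp_high) / (o_low / exp_low)
        se = math.sqrt(1.0 / exp_high + 1.0 / exp_low)
        ci = (hr * math.exp(-1.96 * se), hr * math.exp(1.96 * se))
    return LogrankResult(
        chi2=float(chi2), p=p, hr=float(hr), ci95=ci,
        observed=(o_high, o_low), expected=(exp_high, exp_low),
        hr_unbounded=unbounded,
    )


def records_from_frame(df: pd.DataFrame) -> list[SurvivalRecord]:
    """Build records from a DataFrame with columns subject, time, event,
    expression."""
    return [
        SurvivalRecord(str(r.subject), float(r.time), int(r.event), float(r.expression))
        for r in df.itertuples()
    ]
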