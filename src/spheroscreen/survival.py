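"""Progression-free survival comparison of predicted response groups.

Kaplan–Meier product-limit curves with medians, the Gehan–Breslow
generalized Wilcoxon test (a weighted log-rank with weight equal to the
number at risk, emphasizing early differences), and a Mantel–Haenszel
(log-rank O/E) hazard ratio with a log-scale normal confidence interval.
The PFS clock starts at surgery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "PredictionGroup",
    "SurvivalRecord",
    "KMCurve",
    "HazardRatioResult",
    "SurvivalComparison",
    "UndefinedTestError",
    "km_estimate",
    "gehan_wilcoxon_test",
    "hazard_ratio",
    "compare_groups",
]


class UndefinedTestError(ValueError):
    """Survival comparison is undefined (e.g. no events anywhere)."""


class PredictionGroup(str, Enum):
    PREDICTED_RESPONDER = "predicted_responder"
    PREDICTED_NONRESPONDER = "predicted_nonresponder"


@dataclass(frozen=True)
class SurvivalRecord:
    """Months from surgery to progression (event=True) or censoring."""

    patient_id: str
    time: float
    event: bool
    group: PredictionGroup

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be positive")


@dataclass(frozen=True)
class KMCurve:
    """Right-continuous step function starting at S(0)=1."""

    times: tuple[float, ...]
    survival: tuple[float, ...]
    median: float | None  # None when the curve never reaches 0.5


@dataclass(frozen=True)
class HazardRatioResult:
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    degenerate: bool  # a group had zero events; CI unreliable


@dataclass(frozen=True)
class SurvivalComparison:
    median_by_group: dict[PredictionGroup, float | None]
    wilcoxon_p: float
    hazard_ratio: HazardRatioResult


def _arrays(records: Sequence[SurvivalRecord]) -> tuple[np.ndarray, np.ndarray]:
    t = np.array([r.time for r in records], dtype=float)
    e = np.array([r.event for r in records], dtype=bool)
    return t, e


def km_estimate(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Product-limit survival estimate with the first-crossing median.

    The median is the first time at which the estimated survival drops to
    0.5 or below, undefined (None) when the curve never gets there.
    """
    if not records:
        raise ValueError("need at least one survival record")
    t, e = _arrays(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    times = tuple(float(x) for x in sf.index[1:])  # drop the t=0 anchor
    surv = tuple(float(x) for x in sf.iloc[1:, 0])
    # first crossing of 0.5, with a tolerance so an exact product-limit
    # value of 1/2 (e.g. n events, no censoring, n even) counts as crossed
    median = next(
        (t for t, s in zip(times, surv) if s <= 0.5 + 1e-9), None
    )
    return KMCurve(times=times, survival=surv, median=median)


def gehan_wilcoxon_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> float:
    """Two-sided Gehan–Breslow–Wilcoxon p-value comparing two groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    if not ea.any() and not eb.any():
        raise UndefinedTestError("no events in either group")
    res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb,
                       weightings="wilcoxon")
    return float(res.p_value)


def hazard_ratio(
    group_a: Sequence[SurvivalRecord],
    group_b: Sequence[SurvivalRecord],
    level: float = 0.95,
) -> HazardRatioResult:
    """Mantel–Haenszel hazard ratio of group A relative to group B.

    HR = (O_A/E_A)/(O_B/E_B) with observed and log-rank-expected event
    counts accumulated over the distinct event times; the CI uses the
    normal approximation on the log scale with SE = sqrt(1/E_A + 1/E_B).
    A group with zero events makes the ratio and CI degenerate; the
    result is returned flagged rather than raised.
    """
    from scipy.stats import norm

    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ta, ea = _arrays(group_a)
    tb, eb = _arrays(group_b)
    oa, ob = float(ea.sum()), float(eb.sum())

    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    e_a = e_b = 0.0
    for t in event_times:
        na = float((ta >= t).sum())
        nb = float((tb >= t).sum())
        d = float(((ta == t) & ea).sum() + ((tb == t) & eb).sum())
        n = na + nb
        if n > 0:
            e_a += d * na / n
            e_b += d * nb / n

    degenerate = oa == 0 or ob == 0 or e_a == 0 or e_b == 0
    if degenerate:
        hr = math.inf if ob == 0 and oa > 0 else 0.0 if oa == 0 and ob > 0 else math.nan
        return HazardRatioResult(hr, math.nan, math.nan, True)
    hr = (oa / e_a) / (ob / e_b)
    z = float(norm.ppf(0.5 + level / 2.0))
    se = math.sqrt(1.0 / e_a + 1.0 / e_b)
    return HazardRatioResult(
        hazard_ratio=hr,
        ci_lower=hr * math.exp(-z * se),
        ci_upper=hr * math.exp(z * se),
        degenerate=False,
    )


def compare_groups(records: Sequence[SurvivalRecord]) -> SurvivalComparison:
    """Full PFS comparison of predicted Responders vs Non-Responders."""
    groups = {
        g: [r for r in records if r.group is g] for g in PredictionGroup
    }
    resp = groups[PredictionGroup.PREDICTED_RESPONDER]
    nonresp = groups[PredictionGroup.PREDICTED_NONRESPONDER]
    medians = {g: (km_estimate(rs).median if rs else None) for g, rs in groups.items()}
    return SurvivalComparison(
        median_by_group=medians,
        wilcoxon_p=gehan_wilcoxon_test(resp, nonresp),
        hazard_ratio=hazard_ratio(resp, nonresp),
    )
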