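"""Cohort-relative IC50 thresholding and per-drug response calls.

For most drugs the cohort's uncensored IC50 distribution defines a ternary
call: Responder below the 25th percentile, Moderate between the 25th and
75th, Non-Responder at or above the 75th.  Carboplatin, for which binary
clinical follow-up exists, uses a single cutoff — either the cohort median
or the Youden-optimal ROC cutoff when clinical labels are supplied.
Censored (above-range / failed-fit) IC50s never enter the quantile
derivation and are always called Non-Responder.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .dose_response import IC50Censoring, IC50Estimate

__all__ = [
    "ThresholdMode",
    "ResponseCategory",
    "DrugThresholdSet",
    "ResponseCall",
    "ROCResult",
    "QuantileConfig",
    "InsufficientCohortError",
    "UndefinedAUCError",
    "derive_quartile_thresholds",
    "classify_response",
    "roc_auc",
]


class InsufficientCohortError(ValueError):
    """Too few uncensored IC50s to derive cohort thresholds."""


class UndefinedAUCError(ValueError):
    """ROC analysis needs both outcome classes present."""


class ThresholdMode(str, Enum):
    BINARY = "binary"
    TERNARY = "ternary"


class ResponseCategory(str, Enum):
    RESPONDER = "Responder"
    MODERATE = "Moderate"
    NON_RESPONDER = "NonResponder"


@dataclass(frozen=True)
class DrugThresholdSet:
    """Lower/upper IC50 cutoffs in µM; binary mode has lower == upper."""

    drug: str
    mode: ThresholdMode
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower <= self.upper):
            raise ValueError("thresholds must satisfy 0 < lower <= upper")
        if self.mode is ThresholdMode.BINARY and self.lower != self.upper:
            raise ValueError("binary mode requires a single cutoff")


@dataclass(frozen=True)
class ResponseCall:
    drug: str
    category: ResponseCategory
    ic50: IC50Estimate


@dataclass(frozen=True)
class ROCResult:
    auc: float
    chosen_cutoff: float
    operating_sensitivity: float
    operating_specificity: float


@dataclass(frozen=True)
class QuantileConfig:
    """Quantile levels for cutoff derivation.

    Exact quantiles with linear interpolation between order statistics
    (numpy's default) stand in for the approximate quartiles of manual
    practice; the levels are configurable per study.
    """

    lower: float = 0.25
    upper: float = 0.75
    binary_level: float = 0.5
    min_uncensored: int = 4


def _uncensored_values(estimates: Sequence[IC50Estimate]) -> np.ndarray:
    return np.array(
        [e.value for e in estimates if e.censoring is IC50Censoring.NONE],
        dtype=float,
    )


def derive_quartile_thresholds(
    cohort_ic50s: Mapping[str, Sequence[IC50Estimate]],
    config: QuantileConfig | None = None,
    modes: Mapping[str, ThresholdMode] | None = None,
) -> dict[str, DrugThresholdSet]:
    """Derive per-drug cutoffs from a cohort's uncensored IC50s.

    ``modes`` marks drugs as binary (single cutoff at ``binary_level``);
    everything else is ternary with cutoffs at the configured lower/upper
    quantiles.
    """
    config = config or QuantileConfig()
    modes = modes or {}
    out: dict[str, DrugThresholdSet] = {}
    for drug, estimates in cohort_ic50s.items():
        values = _uncensored_values(estimates)
        if values.size < config.min_uncensored:
            raise InsufficientCohortError(
                f"{drug}: only {values.size} uncensored IC50s, need "
                f"{config.min_uncensored}"
            )
        mode = modes.get(drug, ThresholdMode.TERNARY)
        if mode is ThresholdMode.BINARY:
            cut = float(np.quantile(values, config.binary_level))
            out[drug] = DrugThresholdSet(drug, mode, cut, cut)
        else:
            lo = float(np.quantile(values, config.lower))
            hi = float(np.quantile(values, config.upper))
            out[drug] = DrugThresholdSet(drug, mode, lo, hi)
    return out


def classify_response(
    ic50: IC50Estimate, thresholds: DrugThresholdSet
) -> ResponseCall:
    """Call one drug's response category from its censored IC50 estimate.

    Ternary boundaries are half-open: [lower, upper) is Moderate, so an
    IC50 exactly at the lower cutoff is Moderate and one at the upper
    cutoff is Non-Responder.  Above-range and failed-fit censoring always
    yield Non-Responder; below-range censoring is anomalous and refused.
    """
    if ic50.drug and ic50.drug != thresholds.drug:
        raise ValueError(
            f"IC50 for {ic50.drug!r} classified against {thresholds.drug!r} thresholds"
        )
    if ic50.censoring in (IC50Censoring.ABOVE_RANGE, IC50Censoring.FIT_FAILED):
        return ResponseCall(thresholds.drug, ResponseCategory.NON_RESPONDER, ic50)
    if ic50.censoring is IC50Censoring.BELOW_RANGE:
        raise ValueError(
            f"{thresholds.drug}: below-range IC50 flagged anomalous; "
            "review the curve before calling a response"
        )
    value = ic50.value
    assert value is not None
    if thresholds.mode is ThresholdMode.BINARY:
        cat = (
            ResponseCategory.RESPONDER
            if value < thresholds.lower
            else ResponseCategory.NON_RESPONDER
        )
    elif value < thresholds.lower:
        cat = ResponseCategory.RESPONDER
    elif value < thresholds.upper:
        cat = ResponseCategory.MODERATE
    else:
        cat = ResponseCategory.NON_RESPONDER
    return ResponseCall(thresholds.drug, cat, ic50)


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC analysis for IC50 scores where LOW values indicate response.

    The AUC is the rank (concordance) statistic — the probability that a
    randomly chosen positive has a lower IC50 than a randomly chosen
    negative, ties counting one half — computed through the Mann–Whitney
    U statistic.  The operating cutoff maximizes Youden's J; calls use the
    same half-open convention as classification (score < cutoff is
    positive).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    pos = scores[labels]
    neg = scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise UndefinedAUCError("both outcome classes must be present")

    u = mannwhitneyu(neg, pos, alternative="two-sided").statistic
    auc = float(u) / (pos.size * neg.size)

    # Candidate cutoffs: midpoints between adjacent distinct scores plus
    # the open ends, so every achievable (sens, spec) pair is visited.
    distinct = np.unique(scores)
    mids = (distinct[:-1] + distinct[1:]) / 2.0
    candidates = np.concatenate(([distinct[0]], mids, [distinct[-1] * 2 + 1]))
    best = None
    for cut in candidates:
        sens = float(np.mean(pos < cut))
        spec = float(np.mean(neg >= cut))
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, float(cut), sens, spec)
    assert best is not None
    return ROCResult(
        auc=auc,
        chosen_cutoff=best[1],
        operating_sensitivity=best[2],
        operating_specificity=best[3],
    )
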