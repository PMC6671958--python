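"""Diagnostic concordance between assay predictions and clinical outcomes.

Predictions and outcomes are crossed into a 2x2 confusion matrix from
which the standard test-accuracy statistics are computed: accuracy,
sensitivity and specificity with Wilson score 95% confidence intervals,
a two-sided Fisher exact p-value, and the diagnostic odds ratio with
Haldane–Anscombe correction when any cell is zero.  An exploratory
pre-surgery CA-125 disqualifier (default < 60 U/mL) can filter the cohort
before the statistics are recomputed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ConfusionMatrix",
    "DiagnosticSummary",
    "build_confusion",
    "wilson_ci",
    "fisher_exact_two_sided",
    "diagnostic_summary",
    "apply_ca125_disqualifier",
    "CA125_DISQUALIFIER_CUTOFF",
]

logger = logging.getLogger(__name__)

#: Exploratory pre-surgery CA-125 disqualifier cutoff, U/mL.
CA125_DISQUALIFIER_CUTOFF = 60.0


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts; positive = predicted Responder & responded."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one patient")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticSummary:
    accuracy: float  # percent
    sensitivity: float  # percent
    sensitivity_ci: tuple[float, float]
    specificity: float  # percent
    specificity_ci: tuple[float, float]
    fisher_p: float
    dor: float
    dor_corrected: bool


def build_confusion(
    predictions: Mapping[str, bool], outcomes: Mapping[str, bool]
) -> ConfusionMatrix:
    """Cross per-patient predictions (True = predicted Responder) with
    clinical outcomes (True = clinical responder) over identical patient
    sets."""
    if set(predictions) != set(outcomes):
        only_p = set(predictions) - set(outcomes)
        only_o = set(outcomes) - set(predictions)
        raise ValueError(
            f"patient sets differ (prediction-only: {sorted(only_p)}, "
            f"outcome-only: {sorted(only_o)})"
        )
    tp = fp = fn = tn = 0
    for pid, pred in predictions.items():
        out = outcomes[pid]
        if pred and out:
            tp += 1
        elif pred and not out:
            fp += 1
        elif not pred and out:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def wilson_ci(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion, in %.

    Well-behaved at observed proportions of 0 or 1, where the Wald
    interval collapses.
    """
    if trials <= 0:
        raise ValueError("trials must be positive")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    lo, hi = proportion_confint(successes, trials, alpha=1 - level, method="wilson")
    return float(lo * 100.0), float(hi * 100.0)


def fisher_exact_two_sided(cm: ConfusionMatrix) -> float:
    """Two-sided Fisher exact p for the 2x2 table with fixed margins:
    the sum of hypergeometric point probabilities no larger than the
    observed table's."""
    return float(fisher_exact([[cm.tp, cm.fp], [cm.fn, cm.tn]])[1])


def diagnostic_summary(cm: ConfusionMatrix, level: float = 0.95) -> DiagnosticSummary:
    """All cohort-level accuracy statistics from one confusion matrix.

    The diagnostic odds ratio (TP*TN)/(FP*FN) receives the
    Haldane–Anscombe +0.5 on every cell when any cell is zero, and the
    correction is flagged.
    """
    if cm.tp + cm.fn == 0 or cm.tn + cm.fp == 0:
        raise ValueError("both clinical outcome classes must be represented")
    accuracy = 100.0 * (cm.tp + cm.tn) / cm.total
    sensitivity = 100.0 * cm.tp / (cm.tp + cm.fn)
    specificity = 100.0 * cm.tn / (cm.tn + cm.fp)
    corrected = 0 in (cm.tp, cm.fp, cm.fn, cm.tn)
    shift = 0.5 if corrected else 0.0
    dor = ((cm.tp + shift) * (cm.tn + shift)) / ((cm.fp + shift) * (cm.fn + shift))
    return DiagnosticSummary(
        accuracy=accuracy,
        sensitivity=sensitivity,
        sensitivity_ci=wilson_ci(cm.tp, cm.tp + cm.fn, level),
        specificity=specificity,
        specificity_ci=wilson_ci(cm.tn, cm.tn + cm.fp, level),
        fisher_p=fisher_exact_two_sided(cm),
        dor=float(dor),
        dor_corrected=corrected,
    )


def apply_ca125_disqualifier(
    cohort: pd.DataFrame,
    cutoff: float = CA125_DISQUALIFIER_CUTOFF,
    ca125_column: str = "ca125_presurgery_u_ml",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter a cohort table to patients with pre-surgery CA-125 >= cutoff.

    Returns (retained, removed).  Rows with a missing CA-125 are warned
    about, flagged, and retained (never silently filtered on absent data).
    If ``predicted`` and ``responder`` boolean columns are present the
    removed table gains a ``cell`` column naming each removed patient's
    confusion-matrix membership.
    """
    if ca125_column not in cohort.columns:
        raise ValueError(f"cohort table lacks a {ca125_column!r} column")
    ca = pd.to_numeric(cohort[ca125_column], errors="coerce")
    missing = ca.isna()
    if missing.any():
        for pid in cohort.loc[missing, "patient_id"]:
            logger.warning("%s: missing pre-surgery CA-125; excluded from filtering", pid)
    keep = (ca >= cutoff) | missing
    retained = cohort[keep].copy()
    retained["ca125_filter_skipped"] = missing[keep].to_numpy()
    removed = cohort[~keep].copy()
    if {"predicted", "responder"} <= set(removed.columns):
        removed["cell"] = [
            ("TP" if p and r else "FP" if p else "FN" if r else "TN")
            for p, r in zip(removed["predicted"].astype(bool), removed["responder"].astype(bool))
        ]
    return retained, removed
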