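"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from spheroscreen.dose_response import WellRecord, WellRole


def make_plate(
    viability_by_dose: dict[float, list[float]],
    drug: str = "drugx",
    vehicle_rlu: float = 10000.0,
    n_vehicle: int = 7,
    n_blank: int = 7,
    blank_rlu: float = 100.0,
    plate_id: str = "P1",
) -> list[WellRecord]:
    """Build a plate whose drug wells realize given viability fractions."""
    wells = []
    k = 0
    for _ in range(n_vehicle):
        k += 1
        wells.append(WellRecord(plate_id, f"W{k}", WellRole.VEHICLE, rlu=vehicle_rlu))
    for _ in range(n_blank):
        k += 1
        wells.append(WellRecord(plate_id, f"W{k}", WellRole.BLANK, rlu=blank_rlu))
    for conc, fractions in viability_by_dose.items():
        for v in fractions:
            k += 1
            wells.append(
                WellRecord(
                    plate_id, f"W{k}", WellRole.DRUG,
                    drug=drug, concentration=conc, rlu=v * vehicle_rlu,
                )
            )
    return wells


def fisher_two_sided_enumeration(tp: int, fp: int, fn: int, tn: int) -> float:
    """Brute-force two-sided Fisher exact p by hypergeometric enumeration.

    Fix the margins, enumerate every admissible table, and sum the point
    probabilities no greater than the observed table's (within a 1e-7
    relative tie tolerance).
    """
    r1, r2 = tp + fp, fn + tn
    c1 = tp + fn
    total = r1 + r2

    def log_choose(n: int, k: int) -> float:
        return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)

    denom = log_choose(total, c1)

    def point_prob(a: int) -> float:
        b = r1 - a
        c = c1 - a
        d = r2 - c
        if min(b, c, d) < 0:
            return 0.0
        return math.exp(log_choose(r1, a) + log_choose(r2, c) - denom)

    p_obs = point_prob(tp)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    return sum(
        p for a in range(lo, hi + 1)
        if (p := point_prob(a)) <= p_obs * (1 + 1e-7)
    )


def auc_pair_counting(scores, labels) -> float:
    """Brute-force concordance AUC: low score = positive, ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p < n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


@pytest.fixture
def encoded_adjuvant_cohort() -> pd.DataFrame:
    """The 35-patient adjuvant cohort encoded from its published counts.

    26 TP (two of them with pre-surgery CA-125 below 60 U/mL), 4 FN (all
    with CA-125 between 18 and 58), 5 TN (CA-125 well above 60), 0 FP.
    """
    rows = []

    def add(n, predicted, responder, ca125_values, tag):
        for i, ca in enumerate(ca125_values):
            rows.append(
                dict(
                    patient_id=f"{tag}{i + 1:02d}",
                    predicted=predicted,
                    responder=responder,
                    ca125_presurgery_u_ml=ca,
                )
            )

    add(24, True, True, [150.0 + 10 * i for i in range(24)], "TPhi")
    add(2, True, True, [15.0, 42.0], "TPlo")
    add(4, False, True, [18.0, 35.0, 47.0, 58.0], "FN")
    add(5, False, False, [151.4, 500.0, 1200.0, 4000.0, 9796.0], "TN")
    return pd.DataFrame(rows)
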