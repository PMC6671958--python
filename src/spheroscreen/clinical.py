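"""Real-world clinical outcome classification.

Adjuvant-arm patients (chemotherapy after primary debulking surgery) are
classified responder / non-responder from imaging and serum CA-125 at a
fixed window after chemotherapy completion — six months by default, with
imaging taking precedence over CA-125 because the biomarker is unreliable
in a minority of patients.  Progression within the first three months of
treatment additionally flags the disease as refractory.

Neoadjuvant-arm patients (chemotherapy between laparoscopic biopsy and
interval debulking) are classified by RECIST 1.1 from the change in the
sum of target-lesion diameters: CR and PR count as clinical response, SD
and PD as non-response.

All times are plain month numbers on a single axis starting at treatment
(chemotherapy) start; ``chemo_end_month`` locates completion on that axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

__all__ = [
    "ImagingStatus",
    "RecistCategory",
    "AdjuvantFollowUp",
    "RECISTAssessment",
    "ClinicalOutcome",
    "UnclassifiableError",
    "CA125_RESPONSE_CUTOFF",
    "classify_adjuvant_outcome",
    "classify_recist",
    "neoadjuvant_outcome",
]

#: Conventional serum CA-125 normal/abnormal boundary, U/mL.
CA125_RESPONSE_CUTOFF = 35.0

#: Progression at or before this many months from treatment start is refractory.
REFRACTORY_WINDOW_MONTHS = 3.0


class UnclassifiableError(ValueError):
    """Follow-up is too short to classify the outcome."""


class ImagingStatus(str, Enum):
    NED = "NED"  # no evidence of disease
    STABLE = "stable"
    PROGRESSION = "progression"


class RecistCategory(str, Enum):
    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"


@dataclass(frozen=True)
class AdjuvantFollowUp:
    """Post-surgery follow-up series, times in months from chemo start."""

    patient_id: str
    chemo_end_month: float
    ca125_series: tuple[tuple[float, float], ...]
    imaging_series: tuple[tuple[float, ImagingStatus], ...]
    months_followed: float  # months of follow-up after chemo end


@dataclass(frozen=True)
class RECISTAssessment:
    """Target-lesion diameter sums (mm) at baseline and pre-debulking."""

    baseline_sum: float
    followup_sum: float
    all_lesions_resolved: bool = False
    new_lesions: bool = False

    def __post_init__(self) -> None:
        if self.baseline_sum < 0 or self.followup_sum < 0:
            raise ValueError("lesion diameter sums must be non-negative")
        if self.all_lesions_resolved and self.followup_sum != 0:
            raise ValueError("resolved lesions imply a zero follow-up sum")


@dataclass(frozen=True)
class ClinicalOutcome:
    patient_id: str
    responder: bool
    refractory: bool = False
    recist: RecistCategory | None = None


def classify_adjuvant_outcome(
    fu: AdjuvantFollowUp, eval_month: float = 6.0
) -> ClinicalOutcome:
    """Classify an adjuvant patient at ``eval_month`` months post-chemo.

    Non-responder iff imaging shows progression at or before the
    evaluation point, or — with no imaging available in the window —
    CA-125 exceeds 35 U/mL at evaluation.  A non-progressing imaging
    assessment (NED or stable) outweighs an elevated CA-125.  CA-125
    exactly at 35 classifies as responder.  Refractory means progression
    within the first three months of treatment.
    """
    if fu.months_followed < eval_month:
        raise UnclassifiableError(
            f"{fu.patient_id}: {fu.months_followed} months of follow-up, "
            f"need {eval_month}"
        )
    eval_time = fu.chemo_end_month + eval_month
    imaging = sorted(
        (t, s) for t, s in fu.imaging_series if t <= eval_time
    )
    progression = [t for t, s in imaging if s is ImagingStatus.PROGRESSION]
    refractory = any(t <= REFRACTORY_WINDOW_MONTHS for t in progression)
    if progression:
        return ClinicalOutcome(fu.patient_id, responder=False, refractory=refractory)
    if imaging:
        # latest assessment is NED or stable: imaging outweighs CA-125
        return ClinicalOutcome(fu.patient_id, responder=True)
    ca = sorted((t, v) for t, v in fu.ca125_series if t <= eval_time)
    if not ca:
        raise UnclassifiableError(
            f"{fu.patient_id}: no imaging or CA-125 by month {eval_time:g}"
        )
    latest_ca = ca[-1][1]
    return ClinicalOutcome(fu.patient_id, responder=latest_ca <= CA125_RESPONSE_CUTOFF)


def classify_recist(a: RECISTAssessment) -> RecistCategory:
    """RECIST 1.1 category from target-lesion diameter sums.

    CR: every lesion resolved and no new lesions.  PD: new lesions, or a
    relative increase of at least 20% that is also at least 5 mm absolute.
    PR: at least a 30% reduction (and not CR).  SD otherwise.
    """
    if a.baseline_sum <= 0 and not a.all_lesions_resolved:
        raise ValueError("baseline sum must be positive unless lesions resolved")
    if a.all_lesions_resolved and not a.new_lesions:
        return RecistCategory.CR
    if a.new_lesions:
        return RecistCategory.PD
    change = a.followup_sum - a.baseline_sum
    rel = change / a.baseline_sum
    if rel >= 0.20 and change >= 5.0:
        return RecistCategory.PD
    if rel <= -0.30:
        return RecistCategory.PR
    return RecistCategory.SD


def neoadjuvant_outcome(
    recist: RecistCategory, patient_id: str = ""
) -> ClinicalOutcome:
    """CR/PR count as clinical response; SD/PD as non-response."""
    responder = recist in (RecistCategory.CR, RecistCategory.PR)
    return ClinicalOutcome(patient_id, responder=responder, recist=recist)
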