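"""Patient-level regimen response prediction.

A patient is predicted to respond to their first-line regimen when the
assay called Responder for at least one drug they actually received and
that was tested; a Moderate call never counts as support.  Drugs received
in the clinic but never tested are listed and logged, but contribute
nothing to the prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Sequence

from .response_calling import ResponseCall, ResponseCategory

__all__ = [
    "PatientTestProfile",
    "PredictedResponse",
    "RegimenPrediction",
    "UnpredictablePatientError",
    "predict_regimen_response",
]

logger = logging.getLogger(__name__)

#: The minimum panel for a successful test.
CORE_DRUGS = ("carboplatin", "paclitaxel")


class UnpredictablePatientError(ValueError):
    """No overlap between the drugs received and the drugs tested."""


class PredictedResponse(str, Enum):
    RESPONDER = "Responder"
    NON_RESPONDER = "NonResponder"


@dataclass(frozen=True)
class PatientTestProfile:
    patient_id: str
    calls: Mapping[str, ResponseCall]


@dataclass(frozen=True)
class RegimenPrediction:
    patient_id: str
    predicted: PredictedResponse
    supporting_drugs: tuple[str, ...]
    untested_received_drugs: tuple[str, ...]


def predict_regimen_response(
    profile: PatientTestProfile, regimen: Sequence[str]
) -> RegimenPrediction:
    """Collapse per-drug calls into one Responder/Non-Responder prediction.

    Only the intersection of the regimen with the tested panel matters;
    the prediction is Responder iff that intersection contains at least
    one Responder call.
    """
    if not regimen:
        raise ValueError("regimen must be non-empty")
    regimen_norm = [d.strip().lower() for d in regimen]
    tested = {d.lower(): call for d, call in profile.calls.items()}

    overlap = [d for d in regimen_norm if d in tested]
    untested = tuple(d for d in regimen_norm if d not in tested)
    if not overlap:
        raise UnpredictablePatientError(
            f"{profile.patient_id}: none of the received drugs "
            f"{regimen_norm} were tested"
        )
    if untested:
        logger.warning(
            "%s: drugs received but not tested ignored: %s",
            profile.patient_id,
            ", ".join(untested),
        )
    supporting = tuple(
        d for d in overlap if tested[d].category is ResponseCategory.RESPONDER
    )
    predicted = (
        PredictedResponse.RESPONDER if supporting else PredictedResponse.NON_RESPONDER
    )
    return RegimenPrediction(
        patient_id=profile.patient_id,
        predicted=predicted,
        supporting_drugs=supporting,
        untested_received_drugs=untested,
    )
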