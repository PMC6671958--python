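"""End-to-end cohort analysis: plates in, diagnostics and survival out.

Binds the stage modules into the study workflow: per-plate QC, curve
fitting and censored IC50 estimation; cohort-level threshold derivation
and per-drug calls; regimen prediction; clinical outcome classification;
concordance statistics; PFS comparison.  QC failures are first-class
results reported per plate, never fatal for the cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import pandas as pd

from .clinical import ClinicalOutcome, classify_adjuvant_outcome, classify_recist, neoadjuvant_outcome
from .concordance import ConfusionMatrix, DiagnosticSummary, build_confusion, diagnostic_summary
from .dose_response import (
    FitConfig,
    IC50Estimate,
    QCThresholds,
    QCVerdict,
    WellRecord,
    estimate_ic50,
    fit_4pl,
    normalize_plate,
    run_qc,
)
from .io import followup_from_row, frame_to_wells, recist_from_row
from .regimen import PatientTestProfile, PredictedResponse, RegimenPrediction, predict_regimen_response
from .response_calling import (
    DrugThresholdSet,
    QuantileConfig,
    ThresholdMode,
    classify_response,
)
from .response_calling import derive_quartile_thresholds
from .survival import (
    PredictionGroup,
    SurvivalComparison,
    SurvivalRecord,
    compare_groups,
)

__all__ = [
    "PipelineResult",
    "default_patient_of_plate",
    "estimate_cohort_ic50s",
    "call_cohort",
    "predict_cohort",
    "classify_cohort_outcomes",
    "survival_records",
    "run_pipeline",
]


def default_patient_of_plate(plate_id: str) -> str:
    """Plates named ``<patient>-<drug>`` map back to their patient."""
    return plate_id.rsplit("-", 1)[0]


@dataclass
class PipelineResult:
    qc: dict[str, QCVerdict]
    ic50s: dict[str, dict[str, IC50Estimate]]
    thresholds: dict[str, DrugThresholdSet]
    calls: dict[str, PatientTestProfile]
    predictions: dict[str, RegimenPrediction]
    outcomes: dict[str, ClinicalOutcome]
    confusion: ConfusionMatrix
    summary: DiagnosticSummary
    survival: SurvivalComparison | None

    def calls_frame(self) -> pd.DataFrame:
        """Per-patient drug-call grid (the report's heatmap table)."""
        rows = []
        for pid, profile in sorted(self.calls.items()):
            row: dict[str, object] = {"patient_id": pid}
            for drug, call in profile.calls.items():
                row[drug] = call.category.value
            rows.append(row)
        return pd.DataFrame(rows)


def estimate_cohort_ic50s(
    plates: pd.DataFrame | Sequence[WellRecord],
    qc_thresholds: QCThresholds | None = None,
    fit_config: FitConfig | None = None,
    dose_range: tuple[float, float] = (0.005, 100.0),
    patient_of_plate: Callable[[str], str] = default_patient_of_plate,
) -> tuple[dict[str, dict[str, IC50Estimate]], dict[str, QCVerdict]]:
    """Fit every QC-passing plate; returns (patient -> drug -> IC50, QC)."""
    qc_thresholds = qc_thresholds or QCThresholds()
    wells = frame_to_wells(plates) if isinstance(plates, pd.DataFrame) else list(plates)

    by_plate: dict[str, list[WellRecord]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)

    qc: dict[str, QCVerdict] = {}
    ic50s: dict[str, dict[str, IC50Estimate]] = {}
    for plate_id in sorted(by_plate):
        plate = by_plate[plate_id]
        verdict = run_qc(plate, qc_thresholds)
        qc[plate_id] = verdict
        if not verdict.passed:
            continue
        patient = patient_of_plate(plate_id)
        for drug, curve in normalize_plate(plate).items():
            fit = fit_4pl(curve, fit_config)
            est = estimate_ic50(fit, dose_range=dose_range, drug=drug)
            ic50s.setdefault(patient, {})[drug] = est
    return ic50s, qc


def call_cohort(
    ic50s: Mapping[str, Mapping[str, IC50Estimate]],
    quantile_config: QuantileConfig | None = None,
    modes: Mapping[str, ThresholdMode] | None = None,
) -> tuple[dict[str, DrugThresholdSet], dict[str, PatientTestProfile]]:
    """Derive cohort thresholds and call every patient-drug response."""
    per_drug: dict[str, list[IC50Estimate]] = {}
    for drugs in ic50s.values():
        for drug, est in drugs.items():
            per_drug.setdefault(drug, []).append(est)
    thresholds = derive_quartile_thresholds(per_drug, quantile_config, modes=modes)
    profiles = {
        pid: PatientTestProfile(
            patient_id=pid,
            calls={
                drug: classify_response(est, thresholds[drug])
                for drug, est in drugs.items()
            },
        )
        for pid, drugs in ic50s.items()
    }
    return thresholds, profiles


def predict_cohort(
    profiles: Mapping[str, PatientTestProfile],
    regimens: Mapping[str, Sequence[str]],
) -> dict[str, RegimenPrediction]:
    return {
        pid: predict_regimen_response(profile, regimens[pid])
        for pid, profile in profiles.items()
        if pid in regimens
    }


def classify_cohort_outcomes(
    clinical: pd.DataFrame, eval_month: float = 6.0
) -> dict[str, ClinicalOutcome]:
    """Arm-appropriate outcome classification from the cohort table."""
    outcomes: dict[str, ClinicalOutcome] = {}
    for _, row in clinical.iterrows():
        pid = str(row["patient_id"])
        if str(row["arm"]) == "adjuvant":
            outcomes[pid] = classify_adjuvant_outcome(
                followup_from_row(row), eval_month=eval_month
            )
        else:
            outcomes[pid] = neoadjuvant_outcome(
                classify_recist(recist_from_row(row)), patient_id=pid
            )
    return outcomes


def survival_records(
    clinical: pd.DataFrame,
    predictions: Mapping[str, RegimenPrediction],
) -> list[SurvivalRecord]:
    records = []
    for _, row in clinical.iterrows():
        pid = str(row["patient_id"])
        if pid not in predictions:
            continue
        group = (
            PredictionGroup.PREDICTED_RESPONDER
            if predictions[pid].predicted is PredictedResponse.RESPONDER
            else PredictionGroup.PREDICTED_NONRESPONDER
        )
        records.append(
            SurvivalRecord(
                patient_id=pid,
                time=float(row["pfs_months"]),
                event=bool(int(row["pfs_event"])),
                group=group,
            )
        )
    return records


def run_pipeline(
    plates: pd.DataFrame | Sequence[WellRecord],
    clinical: pd.DataFrame,
    qc_thresholds: QCThresholds | None = None,
    fit_config: FitConfig | None = None,
    quantile_config: QuantileConfig | None = None,
    modes: Mapping[str, ThresholdMode] | None = None,
    dose_range: tuple[float, float] = (0.005, 100.0),
    eval_month: float = 6.0,
    with_survival: bool = True,
) -> PipelineResult:
    """Run the full analysis on a plate table plus a clinical table.

    Binary carboplatin calling is the default mode unless overridden.
    """
    if modes is None:
        modes = {"carboplatin": ThresholdMode.BINARY}
    ic50s, qc = estimate_cohort_ic50s(
        plates, qc_thresholds, fit_config, dose_range=dose_range
    )
    thresholds, profiles = call_cohort(ic50s, quantile_config, modes=modes)
    regimens = {
        str(row["patient_id"]): str(row["drugs_received"]).split(";")
        for _, row in clinical.iterrows()
    }
    predictions = predict_cohort(profiles, regimens)
    outcomes = classify_cohort_outcomes(clinical, eval_month=eval_month)
    shared = sorted(set(predictions) & set(outcomes))
    confusion = build_confusion(
        {p: predictions[p].predicted is PredictedResponse.RESPONDER for p in shared},
        {p: outcomes[p].responder for p in shared},
    )
    summary = diagnostic_summary(confusion)
    survival = None
    if with_survival:
        records = survival_records(clinical, predictions)
        groups = {r.group for r in records}
        if len(groups) == 2 and any(r.event for r in records):
            survival = compare_groups(records)
    return PipelineResult(
        qc=qc,
        ic50s=ic50s,
        thresholds=thresholds,
        calls=profiles,
        predictions=predictions,
        outcomes=outcomes,
        confusion=confusion,
        summary=summary,
        survival=survival,
    )
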