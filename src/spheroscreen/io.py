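"""Delimited-text input/output.

Plate files are comma-delimited with header columns exactly
``plate_id, well_id, role, drug, concentration_um, rlu``; role and drug
parsing is case-insensitive.  Cohort clinical tables carry one row per
patient; time series are encoded as semicolon-separated ``time:value``
pairs in month units.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

from .clinical import AdjuvantFollowUp, ImagingStatus, RECISTAssessment
from .dose_response import WellRecord, WellRole

__all__ = [
    "PLATE_COLUMNS",
    "wells_to_frame",
    "frame_to_wells",
    "read_plate_csv",
    "write_plate_csv",
    "cohort_to_frame",
    "read_cohort_csv",
    "write_cohort_csv",
    "followup_from_row",
    "recist_from_row",
]

PLATE_COLUMNS = ("plate_id", "well_id", "role", "drug", "concentration_um", "rlu")


def wells_to_frame(wells: Iterable[WellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                plate_id=w.plate_id,
                well_id=w.well_id,
                role=w.role.value,
                drug=w.drug or "",
                concentration_um=w.concentration if w.concentration is not None else "",
                rlu=w.rlu,
            )
            for w in wells
        ],
        columns=list(PLATE_COLUMNS),
    )


def _parse_conc(value) -> float | None:
    if value is None or value == "":
        return None
    v = float(value)
    return None if math.isnan(v) else v


def frame_to_wells(df: pd.DataFrame) -> list[WellRecord]:
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table lacks columns: {sorted(missing)}")
    wells = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            role = WellRole(str(row.role).strip().lower())
            drug = str(row.drug).strip().lower() if not pd.isna(row.drug) else ""
            wells.append(
                WellRecord(
                    plate_id=str(row.plate_id),
                    well_id=str(row.well_id),
                    role=role,
                    drug=drug or None,
                    concentration=_parse_conc(row.concentration_um),
                    rlu=float(row.rlu),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"plate table row {i + 2}: {exc}") from exc
    return wells


def read_plate_csv(path) -> list[WellRecord]:
    return frame_to_wells(pd.read_csv(path, keep_default_na=False, na_values=[]))


def write_plate_csv(wells: Iterable[WellRecord], path) -> None:
    wells_to_frame(wells).to_csv(path, index=False)


def _encode_series(series) -> str:
    return ";".join(
        f"{t:.10g}:{v.value if isinstance(v, ImagingStatus) else f'{v:.10g}'}"
        for t, v in series
    )


def _decode_pairs(text: str) -> list[tuple[float, str]]:
    if not text or (isinstance(text, float) and math.isnan(text)):
        return []
    out = []
    for item in str(text).split(";"):
        t, _, v = item.partition(":")
        out.append((float(t), v))
    return out


def cohort_to_frame(patients: Sequence) -> pd.DataFrame:
    """Clinical cohort table from synthetic patients (ground truth omitted)."""
    rows = []
    for p in patients:
        row = dict(
            patient_id=p.patient_id,
            arm=p.arm,
            drugs_received=";".join(p.regimen),
            ca125_presurgery_u_ml=p.ca125_presurgery,
            chemo_end_month="",
            months_followed="",
            ca125_series="",
            imaging_series="",
            recist_baseline_sum_mm="",
            recist_followup_sum_mm="",
            all_lesions_resolved="",
            new_lesions="",
            pfs_months=p.pfs_months,
            pfs_event=int(p.pfs_event),
        )
        if p.followup is not None:
            fu = p.followup
            row.update(
                chemo_end_month=fu.chemo_end_month,
                months_followed=fu.months_followed,
                ca125_series=_encode_series(fu.ca125_series),
                imaging_series=_encode_series(fu.imaging_series),
            )
        if p.recist is not None:
            row.update(
                recist_baseline_sum_mm=p.recist.baseline_sum,
                recist_followup_sum_mm=p.recist.followup_sum,
                all_lesions_resolved=int(p.recist.all_lesions_resolved),
                new_lesions=int(p.recist.new_lesions),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def followup_from_row(row) -> AdjuvantFollowUp:
    ca = tuple((t, float(v)) for t, v in _decode_pairs(row["ca125_series"]))
    imaging = tuple(
        (t, ImagingStatus(v)) for t, v in _decode_pairs(row["imaging_series"])
    )
    return AdjuvantFollowUp(
        patient_id=str(row["patient_id"]),
        chemo_end_month=float(row["chemo_end_month"]),
        ca125_series=ca,
        imaging_series=imaging,
        months_followed=float(row["months_followed"]),
    )


def recist_from_row(row) -> RECISTAssessment:
    return RECISTAssessment(
        baseline_sum=float(row["recist_baseline_sum_mm"]),
        followup_sum=float(row["recist_followup_sum_mm"]),
        all_lesions_resolved=bool(int(row["all_lesions_resolved"])),
        new_lesions=bool(int(row["new_lesions"])),
    )


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[])


def write_cohort_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)
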