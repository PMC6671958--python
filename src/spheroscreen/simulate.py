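"""Seeded synthetic cohort generator.

Produces plate-level luminescence and patient-level clinical follow-up
with the statistical structure the analysis pipeline assumes, so every
stage can be exercised end-to-end without patient data.

Assay side: each patient carries one true 4PL viability curve per panel
drug; plates hold 7 replicate wells per dose on an 8-point log grid from
0.005 to 100 µM plus vehicle, blank and kill-control wells.  Well RLU is
``vehicle_scale * V(c) * (1 + eps)`` with multiplicative mean-zero noise
of standard deviation ``noise_cv`` (plate-reader noise scales with
signal), truncated below at zero.

Ground-truth response categories are cohort-relative by construction: the
same quantile rule the pipeline applies to fitted IC50s is applied to the
true IC50s, because the response categories of this assay are *defined*
by cohort quartiles.  Class IC50 supports are separated by gaps so that a
noiseless analysis recovers every category exactly.

Clinical side: a patient is regimen-sensitive when any received drug is a
true Responder; clinical response is then Bernoulli with linked rates
(1.0 for sensitive, 0.42 for resistant by default).  A configurable
low-CA-125 subgroup (pre-surgery CA-125 < 60 U/mL) responds clinically
regardless of assay class, emulating the false-negative mechanism the
exploratory CA-125 disqualifier targets.  PFS is exponential with
class-specific medians (21 vs 8 months by default) and administrative
censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical import (
    AdjuvantFollowUp,
    ImagingStatus,
    RECISTAssessment,
)
from .dose_response import (
    DEFAULT_DOSE_GRID,
    IC50Censoring,
    IC50Estimate,
    WellRecord,
    WellRole,
    four_pl,
)
from .response_calling import (
    QuantileConfig,
    ResponseCategory,
    ThresholdMode,
    classify_response,
    derive_quartile_thresholds,
)

__all__ = [
    "DrugSensitivityPrior",
    "SimulationConfig",
    "DrugTruth",
    "SyntheticPatient",
    "SyntheticCohort",
    "DEFAULT_DRUG_PANEL",
    "simulate_cohort",
    "simulate_plate",
]

DEFAULT_DRUG_PANEL: tuple[str, ...] = (
    "carboplatin",
    "paclitaxel",
    "doxorubicin",
    "topotecan",
    "gemcitabine",
    "olaparib",
)


@dataclass(frozen=True)
class DrugSensitivityPrior:
    """Mixture over sensitivity classes with log-uniform IC50 supports (µM).

    Supports are disjoint with gaps between classes; the non-responder
    support extends past the top tested dose so a fraction of truly
    resistant curves is censored above range.  Weights follow the
    quartile scheme (25/50/25 ternary; 50/50 binary for carboplatin).
    """

    mode: ThresholdMode = ThresholdMode.TERNARY
    weights: tuple[float, ...] = (0.25, 0.50, 0.25)
    responder_support: tuple[float, float] = (0.01, 0.1)
    moderate_support: tuple[float, float] | None = (0.5, 5.0)
    nonresponder_support: tuple[float, float] = (20.0, 300.0)

    def __post_init__(self) -> None:
        n_classes = 2 if self.mode is ThresholdMode.BINARY else 3
        if len(self.weights) != n_classes:
            raise ValueError("one weight per sensitivity class required")
        if abs(sum(self.weights) - 1.0) > 1e-9 or min(self.weights) < 0:
            raise ValueError("weights must be a probability vector")

    @property
    def supports(self) -> tuple[tuple[float, float], ...]:
        if self.mode is ThresholdMode.BINARY:
            return (self.responder_support, self.nonresponder_support)
        assert self.moderate_support is not None
        return (self.responder_support, self.moderate_support, self.nonresponder_support)


def _default_priors() -> dict[str, DrugSensitivityPrior]:
    priors = {d: DrugSensitivityPrior() for d in DEFAULT_DRUG_PANEL}
    # Carboplatin resistance stays inside the tested window so the binary
    # median cutoff splits the cohort at the mixture weight.
    priors["carboplatin"] = DrugSensitivityPrior(
        mode=ThresholdMode.BINARY,
        weights=(0.5, 0.5),
        responder_support=(0.1, 2.0),
        moderate_support=None,
        nonresponder_support=(20.0, 90.0),
    )
    return priors


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort-level study conditions for the generator."""

    n_patients: int = 44
    adjuvant_fraction: float = 35 / 44
    drug_panel: tuple[str, ...] = DEFAULT_DRUG_PANEL
    sensitivity_priors: Mapping[str, DrugSensitivityPrior] = field(
        default_factory=_default_priors
    )
    dose_grid: tuple[float, ...] = DEFAULT_DOSE_GRID
    replicates: int = 7
    noise_cv: float = 0.10
    vehicle_scale: float = 20000.0
    blank_fraction: float = 0.01
    n_vehicle_wells: int = 14
    n_blank_wells: int = 7
    n_kill_wells: int = 7
    hill_range: tuple[float, float] = (0.8, 2.5)
    bottom_range: tuple[float, float] = (0.0, 0.15)
    regimen: tuple[str, ...] = ("carboplatin", "paclitaxel")
    outcome_link_sensitive: float = 1.0
    outcome_link_resistant: float = 0.42
    low_ca125_fraction: float = 6 / 35
    pfs_median_responder: float = 21.0
    pfs_median_nonresponder: float = 8.0
    censor_horizon_months: float = 36.0
    chemo_end_month: float = 5.0
    refractory_fraction: float = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("adjuvant_fraction", "noise_cv", "outcome_link_sensitive",
                     "outcome_link_resistant", "low_ca125_fraction",
                     "refractory_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if min(self.pfs_median_responder, self.pfs_median_nonresponder) <= 0:
            raise ValueError("PFS medians must be positive")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        lo, hi = min(self.dose_grid), max(self.dose_grid)
        if lo < 0.005 - 1e-12 or hi > 100.0 + 1e-9:
            raise ValueError("dose grid must lie within 0.005-100 µM")


@dataclass(frozen=True)
class DrugTruth:
    """Generating 4PL parameters for one patient-drug pair."""

    ic50: float
    hill: float
    top: float
    bottom: float


@dataclass
class SyntheticPatient:
    patient_id: str
    arm: str  # "adjuvant" | "neoadjuvant"
    regimen: tuple[str, ...]
    truth: dict[str, DrugTruth]
    true_category: dict[str, ResponseCategory]
    regimen_sensitive: bool
    clinical_responder: bool
    low_ca125: bool
    ca125_presurgery: float
    followup: AdjuvantFollowUp | None
    recist: RECISTAssessment | None
    pfs_months: float
    pfs_event: bool
    plates: dict[str, list[WellRecord]] = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    patients: list[SyntheticPatient]

    def truth_table(self) -> pd.DataFrame:
        """Ground truth export; the analysis pipeline never reads this."""
        rows = []
        for p in self.patients:
            for drug, t in p.truth.items():
                rows.append(
                    dict(
                        patient_id=p.patient_id,
                        drug=drug,
                        true_ic50_um=t.ic50,
                        true_hill=t.hill,
                        true_bottom=t.bottom,
                        true_category=p.true_category[drug].value,
                        regimen_sensitive=p.regimen_sensitive,
                        clinical_responder=p.clinical_responder,
                    )
                )
        return pd.DataFrame(rows)

    def plates_frame(self) -> pd.DataFrame:
        from .io import wells_to_frame

        wells = [w for p in self.patients for plate in p.plates.values() for w in plate]
        return wells_to_frame(wells)

    def clinical_frame(self) -> pd.DataFrame:
        from .io import cohort_to_frame

        return cohort_to_frame(self.patients)


def _true_estimate(drug: str, ic50: float, grid: Sequence[float]) -> IC50Estimate:
    if ic50 > max(grid):
        return IC50Estimate(drug, None, IC50Censoring.ABOVE_RANGE)
    if ic50 < min(grid):
        return IC50Estimate(drug, None, IC50Censoring.BELOW_RANGE)
    return IC50Estimate(drug, ic50, IC50Censoring.NONE)


def _assign_true_categories(
    config: SimulationConfig, truths: list[dict[str, DrugTruth]]
) -> list[dict[str, ResponseCategory]]:
    """Cohort-relative ground truth via the quantile rule on true IC50s."""
    modes = {d: p.mode for d, p in config.sensitivity_priors.items()}
    per_drug = {
        d: [_true_estimate(d, t[d].ic50, config.dose_grid) for t in truths]
        for d in config.drug_panel
    }
    thresholds = derive_quartile_thresholds(per_drug, QuantileConfig(), modes=modes)
    out: list[dict[str, ResponseCategory]] = []
    for t in truths:
        cats = {}
        for d in config.drug_panel:
            est = _true_estimate(d, t[d].ic50, config.dose_grid)
            cats[d] = classify_response(est, thresholds[d]).category
        out.append(cats)
    return out


def _draw_truth(
    rng: np.random.Generator, prior: DrugSensitivityPrior, config: SimulationConfig
) -> DrugTruth:
    k = rng.choice(len(prior.weights), p=prior.weights)
    lo, hi = prior.supports[k]
    ic50 = float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))
    return DrugTruth(
        ic50=ic50,
        hill=float(rng.uniform(*config.hill_range)),
        top=1.0,
        bottom=float(rng.uniform(*config.bottom_range)),
    )


def simulate_plate(
    patient_id: str,
    drug: str,
    truth: DrugTruth,
    config: SimulationConfig,
    seed: int | np.random.Generator,
) -> list[WellRecord]:
    """One plate: replicate drug wells on the dose grid plus controls."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plate_id = f"{patient_id}-{drug}"
    scale = config.vehicle_scale

    def rlu(expected: float) -> float:
        noise = rng.normal(0.0, config.noise_cv) if config.noise_cv > 0 else 0.0
        return max(0.0, expected * (1.0 + noise))

    wells: list[WellRecord] = []
    counter = 0

    def add(role: WellRole, value: float, drug_name=None, conc=None) -> None:
        nonlocal counter
        counter += 1
        wells.append(
            WellRecord(
                plate_id=plate_id,
                well_id=f"{plate_id}-W{counter:03d}",
                role=role,
                drug=drug_name,
                concentration=conc,
                rlu=value,
            )
        )

    for _ in range(config.n_vehicle_wells):
        add(WellRole.VEHICLE, rlu(scale))
    for _ in range(config.n_blank_wells):
        add(WellRole.BLANK, rlu(scale * config.blank_fraction))
    for _ in range(config.n_kill_wells):
        add(WellRole.KILL_HIGH, rlu(scale * 0.02))
    for _ in range(config.n_kill_wells):
        add(WellRole.KILL_LOW, rlu(scale * 0.5))
    for c in config.dose_grid:
        expected = scale * float(
            four_pl(c, truth.top, truth.bottom, truth.ic50, truth.hill)
        )
        for _ in range(config.replicates):
            add(WellRole.DRUG, rlu(expected), drug_name=drug, conc=float(c))
    return wells


def _simulate_adjuvant_followup(
    rng: np.random.Generator,
    patient_id: str,
    responder: bool,
    config: SimulationConfig,
) -> tuple[AdjuvantFollowUp, bool]:
    """Follow-up series consistent with the clinical response; returns
    (follow-up, refractory)."""
    eval_time = config.chemo_end_month + 6.0
    if responder:
        fu = AdjuvantFollowUp(
            patient_id=patient_id,
            chemo_end_month=config.chemo_end_month,
            ca125_series=((eval_time, float(rng.uniform(5.0, 30.0))),),
            imaging_series=((eval_time, ImagingStatus.NED),),
            months_followed=float(rng.uniform(6.0, 24.0)),
        )
        return fu, False
    refractory = bool(rng.random() < config.refractory_fraction)
    if refractory:
        prog = float(rng.uniform(0.5, 3.0))
    else:
        prog = float(rng.uniform(config.chemo_end_month + 0.5, eval_time - 0.1))
    fu = AdjuvantFollowUp(
        patient_id=patient_id,
        chemo_end_month=config.chemo_end_month,
        ca125_series=((eval_time, float(rng.uniform(50.0, 800.0))),),
        imaging_series=((prog, ImagingStatus.PROGRESSION),),
        months_followed=float(rng.uniform(6.0, 24.0)),
    )
    return fu, refractory


def _simulate_recist(
    rng: np.random.Generator, responder: bool
) -> RECISTAssessment:
    baseline = float(rng.uniform(30.0, 150.0))
    if responder:
        if rng.random() < 1.0 / 7.0:  # complete responses are the minority
            return RECISTAssessment(baseline, 0.0, all_lesions_resolved=True)
        change = float(rng.uniform(-0.90, -0.35))
        return RECISTAssessment(baseline, baseline * (1.0 + change))
    if rng.random() < 0.4:  # progressive disease
        if rng.random() < 0.5:
            return RECISTAssessment(baseline, baseline, new_lesions=True)
        change = float(rng.uniform(0.25, 0.60))
        return RECISTAssessment(baseline, baseline * (1.0 + change))
    change = float(rng.uniform(-0.25, 0.15))  # stable disease window
    return RECISTAssessment(baseline, baseline * (1.0 + change))


def simulate_cohort(
    config: SimulationConfig | None = None,
    seed: int | None = None,
    include_plates: bool = True,
) -> SyntheticCohort:
    """Generate a reproducible synthetic cohort under ``config``.

    ``seed`` overrides ``config.seed``.  With ``include_plates=False``
    only ground truth and clinical follow-up are generated, which is much
    faster when plate-level data are not needed.
    """
    config = config or SimulationConfig()
    if seed is None:
        seed = config.seed if config.seed is not None else 0
    rng = np.random.default_rng(seed)

    n = config.n_patients
    n_adj = int(round(n * config.adjuvant_fraction))
    ids = [f"SYN{i + 1:04d}" for i in range(n)]

    truths = [
        {
            d: _draw_truth(rng, config.sensitivity_priors[d], config)
            for d in config.drug_panel
        }
        for _ in range(n)
    ]
    categories = _assign_true_categories(config, truths)

    patients: list[SyntheticPatient] = []
    for i, pid in enumerate(ids):
        arm = "adjuvant" if i < n_adj else "neoadjuvant"
        cats = categories[i]
        sensitive = any(
            cats.get(d) is ResponseCategory.RESPONDER for d in config.regimen
        )
        low_ca125 = arm == "adjuvant" and bool(
            rng.random() < config.low_ca125_fraction
        )
        if low_ca125:
            responder = True  # the observed low-CA-125 phenomenon: clinical
            # response regardless of assay class
            ca125 = float(rng.uniform(15.0, 59.0))
        else:
            link = (
                config.outcome_link_sensitive
                if sensitive
                else config.outcome_link_resistant
            )
            responder = bool(rng.random() < link)
            ca125 = float(10.0 ** rng.uniform(2.0, 4.3))  # 100 to ~20000 U/mL

        followup = None
        recist = None
        if arm == "adjuvant":
            followup, _ = _simulate_adjuvant_followup(rng, pid, responder, config)
        else:
            recist = _simulate_recist(rng, responder)

        median = (
            config.pfs_median_responder
            if responder
            else config.pfs_median_nonresponder
        )
        t = float(rng.exponential(median / math.log(2.0)))
        t = max(t, 0.05)
        if t > config.censor_horizon_months:
            pfs, event = config.censor_horizon_months, False
        else:
            pfs, event = t, True

        patients.append(
            SyntheticPatient(
                patient_id=pid,
                arm=arm,
                regimen=config.regimen,
                truth=truths[i],
                true_category=cats,
                regimen_sensitive=sensitive,
                clinical_responder=responder,
                low_ca125=low_ca125,
                ca125_presurgery=ca125,
                followup=followup,
                recist=recist,
                pfs_months=pfs,
                pfs_event=event,
            )
        )

    if include_plates:
        for p in patients:
            for d in config.drug_panel:
                p.plates[d] = simulate_plate(p.patient_id, d, p.truth[d], config, rng)

    return SyntheticCohort(config=config, patients=patients)
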