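"""Plate-level dose-response analytics.

Raw plate-reader luminescence (RLU, proportional to viable-cell ATP) is
taken through quality control, vehicle normalization and four-parameter
logistic (4PL) fitting to produce a censored IC50 estimate per drug.

The viability model is the falling sigmoid

    V(c) = bottom + (top - bottom) / (1 + (c / IC50)**hill),    hill > 0,

fitted by bounded least squares on log10 concentration with multi-start
initialization (the IC50 start is seeded at every tested dose), which is
robust for monotone partial-kill curves.  IC50 values landing outside the
tested concentration window are censored rather than reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "WellRole",
    "WellRecord",
    "QCThresholds",
    "QCVerdict",
    "NormalizedDoseResponse",
    "FourPLParameters",
    "IC50Censoring",
    "IC50Estimate",
    "FitConfig",
    "MalformedPlateError",
    "DegenerateNormalizationError",
    "four_pl",
    "run_qc",
    "normalize_plate",
    "fit_4pl",
    "estimate_ic50",
    "DEFAULT_DOSE_GRID",
]

#: Default 8-point log-spaced dose grid in µM, spanning the tested window.
DEFAULT_DOSE_GRID: tuple[float, ...] = tuple(
    float(c) for c in np.geomspace(0.005, 100.0, 8)
)


class MalformedPlateError(ValueError):
    """Plate is structurally unusable (e.g. missing vehicle or blank wells)."""


class DegenerateNormalizationError(ValueError):
    """Vehicle signal is zero; viability fractions are undefined."""


class WellRole(str, Enum):
    DRUG = "drug"
    VEHICLE = "vehicle"
    BLANK = "blank"
    KILL_HIGH = "kill_high"
    KILL_LOW = "kill_low"


@dataclass(frozen=True)
class WellRecord:
    """One well of a spheroid microplate.

    Drug wells carry a drug name and a positive concentration in µM;
    vehicle/blank/kill-control wells carry neither.  RLU is non-negative.
    """

    plate_id: str
    well_id: str
    role: WellRole
    drug: str | None = None
    concentration: float | None = None
    rlu: float = 0.0

    def __post_init__(self) -> None:
        if self.rlu < 0:
            raise ValueError(f"negative RLU in well {self.well_id}")
        if self.role is WellRole.DRUG:
            if not self.drug:
                raise ValueError(f"drug well {self.well_id} lacks a drug name")
            if self.concentration is None or self.concentration <= 0:
                raise ValueError(
                    f"drug well {self.well_id} needs a positive concentration"
                )
        else:
            if self.drug or self.concentration is not None:
                raise ValueError(
                    f"{self.role.value} well {self.well_id} must not carry "
                    "a drug or concentration"
                )


@dataclass(frozen=True)
class QCThresholds:
    """Assay-success gates applied per plate.

    min_vehicle_rlu is in synthetic RLU units; min_dynamic_range is the
    required vehicle-mean / blank-mean ratio; min_replicates_per_dose is
    the required well count at every tested concentration.
    """

    min_vehicle_rlu: float = 1000.0
    min_dynamic_range: float = 3.0
    min_replicates_per_dose: int = 7

    def __post_init__(self) -> None:
        if min(self.min_vehicle_rlu, self.min_dynamic_range) <= 0:
            raise ValueError("QC thresholds must be strictly positive")
        if self.min_dynamic_range <= 1:
            raise ValueError("min_dynamic_range must exceed 1")
        if self.min_replicates_per_dose < 1:
            raise ValueError("min_replicates_per_dose must be >= 1")


@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


@dataclass(frozen=True)
class NormalizedDoseResponse:
    """Vehicle-normalized viability fractions on an ascending dose grid."""

    drug: str
    concentrations: tuple[float, ...]
    viability: tuple[float, ...]
    replicate_count: tuple[int, ...]
    viability_sd: tuple[float, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations)
        if len(c) != len(self.viability):
            raise ValueError("concentration/viability length mismatch")
        if np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if any(v < 0 for v in self.viability):
            raise ValueError("viability fractions must be non-negative")


@dataclass(frozen=True)
class FourPLParameters:
    top: float
    bottom: float
    ic50: float
    hill: float
    converged: bool
    rss: float


class IC50Censoring(str, Enum):
    NONE = "none"
    ABOVE_RANGE = "above_range"
    BELOW_RANGE = "below_range"
    FIT_FAILED = "fit_failed"


@dataclass(frozen=True)
class IC50Estimate:
    drug: str
    value: float | None
    censoring: IC50Censoring

    def __post_init__(self) -> None:
        if (self.value is not None) != (self.censoring is IC50Censoring.NONE):
            raise ValueError("value must be present iff censoring is none")

    @property
    def is_censored(self) -> bool:
        return self.censoring is not IC50Censoring.NONE


@dataclass(frozen=True)
class FitConfig:
    """Bounded least-squares settings for the 4PL fit.

    top/bottom are bounded to [0, 1.5] so that stimulation above vehicle
    (viability > 1) can still be modelled without letting the plateau run
    away; the IC50 search window extends well past the tested doses so
    off-grid optima are representable and can be censored downstream.
    min_observed_drop declares a curve unidentifiable (converged=False)
    when the data show essentially no response across the tested window.
    """

    top_bounds: tuple[float, float] = (0.0, 1.5)
    bottom_bounds: tuple[float, float] = (0.0, 1.5)
    hill_bounds: tuple[float, float] = (0.1, 10.0)
    ic50_bounds: tuple[float, float] = (1e-5, 1e5)
    min_observed_drop: float = 0.1
    xtol: float = 1e-12
    ftol: float = 1e-12


def four_pl(c, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the four-parameter logistic viability curve at dose(s) c."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def _role_rlus(wells: Iterable[WellRecord], role: WellRole) -> np.ndarray:
    return np.array([w.rlu for w in wells if w.role is role], dtype=float)


def run_qc(wells: Sequence[WellRecord], thresholds: QCThresholds) -> QCVerdict:
    """Gate a plate on vehicle signal, dynamic range and replicate counts.

    Failure reasons enumerate every violated gate; a plate with no vehicle
    or no blank wells is malformed rather than merely failing QC.
    """
    vehicle = _role_rlus(wells, WellRole.VEHICLE)
    blank = _role_rlus(wells, WellRole.BLANK)
    if vehicle.size == 0 or blank.size == 0:
        raise MalformedPlateError("plate requires at least one vehicle and one blank well")

    reasons: list[str] = []
    vehicle_mean = float(vehicle.mean())
    blank_mean = float(blank.mean())
    if vehicle_mean < thresholds.min_vehicle_rlu:
        reasons.append(
            f"vehicle mean RLU {vehicle_mean:.1f} below minimum "
            f"{thresholds.min_vehicle_rlu:.1f}"
        )
    ratio = math.inf if blank_mean == 0 else vehicle_mean / blank_mean
    if ratio < thresholds.min_dynamic_range:
        reasons.append(
            f"dynamic range {ratio:.2f} below minimum "
            f"{thresholds.min_dynamic_range:.2f}"
        )
    counts: dict[tuple[str, float], int] = {}
    for w in wells:
        if w.role is WellRole.DRUG:
            key = (w.drug, w.concentration)  # type: ignore[arg-type]
            counts[key] = counts.get(key, 0) + 1
    for (drug, conc), n in sorted(counts.items()):
        if n < thresholds.min_replicates_per_dose:
            reasons.append(
                f"{drug} at {conc:g} µM has {n} replicates, fewer than "
                f"{thresholds.min_replicates_per_dose}"
            )
    return QCVerdict(passed=not reasons, reasons=tuple(reasons))


def normalize_plate(wells: Sequence[WellRecord]) -> dict[str, NormalizedDoseResponse]:
    """Average replicates per dose and normalize to the vehicle mean.

    Returns one dose-response curve per drug on the plate, with the dose
    grid sorted ascending.  Viability above 1 (stimulation) is retained:
    clipping would bias the fitted top plateau.
    """
    vehicle = _role_rlus(wells, WellRole.VEHICLE)
    if vehicle.size == 0:
        raise MalformedPlateError("no vehicle wells to normalize against")
    vehicle_mean = float(vehicle.mean())
    if vehicle_mean == 0:
        raise DegenerateNormalizationError("vehicle mean RLU is zero")

    by_drug: dict[str, dict[float, list[float]]] = {}
    for w in wells:
        if w.role is WellRole.DRUG:
            by_drug.setdefault(w.drug, {}).setdefault(w.concentration, []).append(w.rlu)

    out: dict[str, NormalizedDoseResponse] = {}
    for drug, doses in by_drug.items():
        if len(doses) < 2:
            raise ValueError(f"{drug}: need at least 2 distinct concentrations")
        grid = sorted(doses)
        means, sds, counts = [], [], []
        for c in grid:
            r = np.asarray(doses[c], dtype=float) / vehicle_mean
            means.append(float(r.mean()))
            sds.append(float(r.std(ddof=1)) if r.size > 1 else 0.0)
            counts.append(int(r.size))
        out[drug] = NormalizedDoseResponse(
            drug=drug,
            concentrations=tuple(grid),
            viability=tuple(means),
            replicate_count=tuple(counts),
            viability_sd=tuple(sds),
        )
    return out


def _fit_residuals(params: np.ndarray, logc: np.ndarray, v: np.ndarray) -> np.ndarray:
    top, bottom, m, hill = params
    pred = bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - m)))
    return pred - v


def fit_4pl(curve: NormalizedDoseResponse, config: FitConfig | None = None) -> FourPLParameters:
    """Least-squares 4PL fit on log10 dose with multi-start IC50 seeding.

    Non-convergence (including an unidentifiable flat curve) is reported
    through ``converged=False``, never as an exception.
    """
    config = config or FitConfig()
    c = np.asarray(curve.concentrations, dtype=float)
    v = np.asarray(curve.viability, dtype=float)
    if c.size < 4:
        raise ValueError("need at least 4 dose points to fit a 4PL")
    logc = np.log10(c)

    observed_drop = float(v.max() - v.min())
    lo = np.array(
        [config.top_bounds[0], config.bottom_bounds[0],
         math.log10(config.ic50_bounds[0]), config.hill_bounds[0]]
    )
    hi = np.array(
        [config.top_bounds[1], config.bottom_bounds[1],
         math.log10(config.ic50_bounds[1]), config.hill_bounds[1]]
    )
    top0 = float(np.clip(v.max(), *config.top_bounds))
    bottom0 = float(np.clip(v.min(), *config.bottom_bounds))
    m_starts = list(logc) + [float(logc.mean())]

    best = None
    for m0 in m_starts:
        x0 = np.clip(np.array([top0, bottom0, m0, 1.0]), lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                _fit_residuals, x0, bounds=(lo, hi), args=(logc, v),
                xtol=config.xtol, ftol=config.ftol, gtol=1e-12,
            )
        except Exception:  # numerical failure on one start is not fatal
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return FourPLParameters(np.nan, np.nan, np.nan, np.nan, False, np.inf)

    top, bottom, m, hill = (float(x) for x in best.x)
    rss = float(2.0 * best.cost)
    identifiable = observed_drop >= config.min_observed_drop and bottom <= top + 1e-9
    return FourPLParameters(
        top=top, bottom=bottom, ic50=float(10.0 ** m), hill=hill,
        converged=bool(identifiable), rss=rss,
    )


def estimate_ic50(
    fit: FourPLParameters,
    dose_range: tuple[float, float] = (0.005, 100.0),
    drug: str = "",
) -> IC50Estimate:
    """Censor a fitted IC50 against the tested concentration window.

    A failed fit is reported as ``fit_failed``; an IC50 above the top
    tested dose as ``above_range`` (called Non-Responder downstream); one
    below the lowest dose as ``below_range``, flagged as anomalous rather
    than silently converted into a response call.
    """
    lo, hi = dose_range
    if not fit.converged or not math.isfinite(fit.ic50):
        return IC50Estimate(drug=drug, value=None, censoring=IC50Censoring.FIT_FAILED)
    if fit.ic50 > hi:
        return IC50Estimate(drug=drug, value=None, censoring=IC50Censoring.ABOVE_RANGE)
    if fit.ic50 < lo:
        return IC50Estimate(drug=drug, value=None, censoring=IC50Censoring.BELOW_RANGE)
    return IC50Estimate(drug=drug, value=float(fit.ic50), censoring=IC50Censoring.NONE)
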