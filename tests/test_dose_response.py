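"""Plate QC, vehicle normalization, 4PL fitting and IC50 censoring."""

import numpy as np
import pytest

from conftest import make_plate
from spheroscreen.dose_response import (
    DEFAULT_DOSE_GRID,
    FitConfig,
    FourPLParameters,
    IC50Censoring,
    MalformedPlateError,
    QCThresholds,
    WellRecord,
    WellRole,
    estimate_ic50,
    fit_4pl,
    four_pl,
    normalize_plate,
    run_qc,
)

GRID = list(DEFAULT_DOSE_GRID)


class TestQC:
    def test_no_signal_window_fails_dynamic_range(self):
        plate = make_plate({0.1: [1.0] * 7, 1.0: [1.0] * 7},
                           vehicle_rlu=5000, blank_rlu=5000)
        verdict = run_qc(plate, QCThresholds(min_dynamic_range=3.0))
        assert not verdict.passed
        assert any("dynamic range" in r for r in verdict.reasons)

    def test_constructed_pass(self):
        plate = make_plate({c: [0.8] * 7 for c in GRID},
                           vehicle_rlu=10000, blank_rlu=1000)
        assert run_qc(plate, QCThresholds()).passed

    def test_underreplicated_dose_fails_replicate_gate(self):
        doses = {c: [0.8] * 7 for c in GRID}
        doses[GRID[3]] = [0.8] * 3
        plate = make_plate(doses)
        verdict = run_qc(plate, QCThresholds(min_replicates_per_dose=7))
        assert not verdict.passed
        assert any("3 replicates" in r for r in verdict.reasons)

    def test_low_vehicle_signal_reported(self):
        plate = make_plate({0.1: [0.8] * 7, 1.0: [0.5] * 7},
                           vehicle_rlu=500, blank_rlu=10)
        verdict = run_qc(plate, QCThresholds(min_vehicle_rlu=1000))
        assert not verdict.passed and any("vehicle mean" in r for r in verdict.reasons)

    def test_missing_controls_is_malformed(self):
        drug_only = [
            WellRecord("P", f"W{i}", WellRole.DRUG, "d", 1.0, 100.0)
            for i in range(7)
        ]
        with pytest.raises(MalformedPlateError):
            run_qc(drug_only, QCThresholds())


class TestNormalization:
    def test_drug_equal_to_vehicle_gives_unit_viability(self):
        plate = make_plate({0.1: [1.0] * 7, 1.0: [1.0] * 7})
        curve = normalize_plate(plate)["drugx"]
        assert curve.viability == (1.0, 1.0)

    def test_full_kill_gives_zero_viability(self):
        plate = make_plate({0.1: [0.0] * 7, 1.0: [0.0] * 7})
        assert normalize_plate(plate)["drugx"].viability == (0.0, 0.0)

    def test_closed_form_half_viability_at_ic50(self):
        # noiseless wells generated from 4PL(top=1, bottom=0, ic50=1, hill=1)
        grid = [0.01, 0.1, 1.0, 10.0, 100.0]
        doses = {c: [float(four_pl(c, 1, 0, 1.0, 1.0))] * 7 for c in grid}
        curve = normalize_plate(make_plate(doses))["drugx"]
        at_1um = curve.viability[curve.concentrations.index(1.0)]
        assert at_1um == pytest.approx(0.5, abs=1e-12)

    def test_grid_sorted_and_counts_recorded(self):
        plate = make_plate({10.0: [0.2] * 7, 0.1: [0.9] * 7, 1.0: [0.5] * 7})
        curve = normalize_plate(plate)["drugx"]
        assert curve.concentrations == (0.1, 1.0, 10.0)
        assert curve.replicate_count == (7, 7, 7)

    def test_well_order_is_irrelevant(self):
        plate = make_plate({c: [0.9 - 0.1 * i for i in range(7)] for c in GRID})
        forward = normalize_plate(plate)["drugx"]
        backward = normalize_plate(plate[::-1])["drugx"]
        assert forward == backward


def _noiseless_curve(top, bottom, ic50, hill, grid=GRID):
    doses = {c: [float(four_pl(c, top, bottom, ic50, hill))] * 7 for c in grid}
    return normalize_plate(make_plate(doses))["drugx"]


class TestFourPLFit:
    def test_unit_curve_round_trip_tight(self):
        fit = fit_4pl(_noiseless_curve(1.0, 0.0, 1.0, 1.0))
        assert fit.converged
        assert fit.ic50 == pytest.approx(1.0, rel=1e-4)

    def test_partial_kill_round_trip(self):
        fit = fit_4pl(_noiseless_curve(1.0, 0.2, 10.0, 2.0))
        assert fit.converged
        assert fit.bottom == pytest.approx(0.2, abs=1e-3)
        assert fit.ic50 == pytest.approx(10.0, rel=1e-3)
        assert fit.hill == pytest.approx(2.0, rel=1e-3)

    def test_flat_curve_is_not_a_convergent_fit(self):
        fit = fit_4pl(_noiseless_curve(1.0, 1.0, 1.0, 1.0))
        est = estimate_ic50(fit, (0.005, 100.0), drug="d")
        assert not fit.converged
        assert est.censoring is IC50Censoring.FIT_FAILED

    def test_parameter_recovery_across_seeded_draws(self):
        # generator round trip over 100 random parameter sets
        rng = np.random.default_rng(42)
        for _ in range(100):
            top = rng.uniform(0.9, 1.1)
            bottom = rng.uniform(0.0, 0.3)
            ic50 = 10.0 ** rng.uniform(np.log10(0.02), np.log10(50.0))
            hill = rng.uniform(0.8, 3.0)
            fit = fit_4pl(_noiseless_curve(top, bottom, ic50, hill))
            assert fit.converged
            assert fit.ic50 == pytest.approx(ic50, rel=1e-3)
            assert fit.hill == pytest.approx(hill, rel=1e-3)

    def test_too_few_doses_rejected(self):
        with pytest.raises(ValueError):
            fit_4pl(_noiseless_curve(1, 0, 1, 1, grid=[0.1, 1.0, 10.0]))

    def test_half_plate_split_agrees_with_full_plate(self):
        # inter-operator reproducibility analogue: split replicates in two
        rng = np.random.default_rng(7)
        doses = {
            c: list(float(four_pl(c, 1, 0.05, 2.0, 1.5)) * (1 + rng.normal(0, 0.05))
                    for _ in range(8))
            for c in GRID
        }
        full = fit_4pl(normalize_plate(make_plate(doses))["drugx"])
        halves = []
        for sel in (slice(0, 4), slice(4, 8)):
            half = {c: v[sel] for c, v in doses.items()}
            halves.append(fit_4pl(normalize_plate(make_plate(half))["drugx"]).ic50)
        assert np.mean(halves) == pytest.approx(full.ic50, rel=0.15)


class TestIC50Censoring:
    @pytest.mark.parametrize(
        "ic50, expected",
        [
            (250.0, IC50Censoring.ABOVE_RANGE),
            (1.0, IC50Censoring.NONE),
            (0.001, IC50Censoring.BELOW_RANGE),
        ],
    )
    def test_censoring_against_tested_window(self, ic50, expected):
        fit = FourPLParameters(1.0, 0.0, ic50, 1.0, converged=True, rss=0.0)
        est = estimate_ic50(fit, (0.005, 100.0), drug="d")
        assert est.censoring is expected
        if expected is IC50Censoring.NONE:
            assert est.value == pytest.approx(ic50)
        else:
            assert est.value is None

    def test_normalizing_normalized_curve_is_identity(self):
        # vehicle at exactly 1.0 leaves drug fractions untouched
        plate = make_plate({c: [0.4] * 7 for c in GRID}, vehicle_rlu=1.0,
                           blank_rlu=0.0)
        curve = normalize_plate(plate)["drugx"]
        assert all(v == pytest.approx(0.4) for v in curve.viability)
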