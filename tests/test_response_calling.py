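"""Quartile threshold derivation, response categories and ROC analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import auc_pair_counting
from spheroscreen.dose_response import IC50Censoring, IC50Estimate
from spheroscreen.response_calling import (
    DrugThresholdSet,
    InsufficientCohortError,
    QuantileConfig,
    ResponseCategory,
    ThresholdMode,
    UndefinedAUCError,
    classify_response,
    derive_quartile_thresholds,
    roc_auc,
)


def est(drug, value=None, censoring=IC50Censoring.NONE):
    if value is None and censoring is IC50Censoring.NONE:
        censoring = IC50Censoring.ABOVE_RANGE
    return IC50Estimate(drug, value, censoring)


class TestThresholdDerivation:
    def test_linear_interpolation_quartiles(self):
        ts = derive_quartile_thresholds({"d": [est("d", v) for v in (1, 2, 3, 4)]})
        assert ts["d"].lower == pytest.approx(1.75)
        assert ts["d"].upper == pytest.approx(3.25)

    def test_degenerate_spread_collapses_thresholds(self):
        ts = derive_quartile_thresholds({"d": [est("d", 2.0)] * 5})
        assert ts["d"].lower == ts["d"].upper == 2.0
        # tie rule: the collapsed boundary itself is Non-Responder
        call = classify_response(est("d", 2.0), ts["d"])
        assert call.category is ResponseCategory.NON_RESPONDER
        assert (
            classify_response(est("d", 1.9), ts["d"]).category
            is ResponseCategory.RESPONDER
        )

    def test_insufficient_uncensored_values(self):
        values = [est("d", 1.0), est("d", 2.0), est("d", 3.0),
                  est("d", censoring=IC50Censoring.ABOVE_RANGE)]
        with pytest.raises(InsufficientCohortError):
            derive_quartile_thresholds({"d": values})

    def test_censored_values_excluded_from_quantiles(self):
        uncensored = [est("d", v) for v in (1, 2, 3, 4)]
        censored = [est("d", censoring=IC50Censoring.ABOVE_RANGE)] * 10
        ts = derive_quartile_thresholds({"d": uncensored + censored})
        assert (ts["d"].lower, ts["d"].upper) == (pytest.approx(1.75), pytest.approx(3.25))

    def test_loguniform_cohort_partitions_5_10_5(self):
        rng = np.random.default_rng(11)
        values = 10.0 ** rng.uniform(-2, 2, size=20)
        ts = derive_quartile_thresholds({"d": [est("d", v) for v in values]})
        calls = [classify_response(est("d", v), ts["d"]).category for v in values]
        assert calls.count(ResponseCategory.RESPONDER) == 5
        assert calls.count(ResponseCategory.MODERATE) == 10
        assert calls.count(ResponseCategory.NON_RESPONDER) == 5

    def test_binary_mode_single_cutoff_at_median(self):
        ts = derive_quartile_thresholds(
            {"carboplatin": [est("carboplatin", v) for v in (1, 2, 3, 4)]},
            modes={"carboplatin": ThresholdMode.BINARY},
        )
        assert ts["carboplatin"].lower == ts["carboplatin"].upper == pytest.approx(2.5)


class TestClassification:
    TS = DrugThresholdSet("d", ThresholdMode.TERNARY, 1.0, 10.0)

    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.1, ResponseCategory.RESPONDER),
            (1.0, ResponseCategory.MODERATE),  # boundary: half-open [lower, upper)
            (5.0, ResponseCategory.MODERATE),
            (10.0, ResponseCategory.NON_RESPONDER),
            (50.0, ResponseCategory.NON_RESPONDER),
        ],
    )
    def test_ternary_partition(self, value, expected):
        assert classify_response(est("d", value), self.TS).category is expected

    @pytest.mark.parametrize(
        "censoring", [IC50Censoring.ABOVE_RANGE, IC50Censoring.FIT_FAILED]
    )
    def test_high_censoring_is_nonresponder(self, censoring):
        call = classify_response(est("d", censoring=censoring), self.TS)
        assert call.category is ResponseCategory.NON_RESPONDER

    def test_below_range_is_refused_not_called(self):
        with pytest.raises(ValueError, match="anomalous"):
            classify_response(est("d", censoring=IC50Censoring.BELOW_RANGE), self.TS)

    def test_drug_mismatch_is_contract_error(self):
        with pytest.raises(ValueError, match="thresholds"):
            classify_response(est("other", 1.0), self.TS)

    def test_binary_never_emits_moderate(self):
        ts = DrugThresholdSet("d", ThresholdMode.BINARY, 2.0, 2.0)
        cats = {classify_response(est("d", v), ts).category for v in (0.5, 2.0, 9.0)}
        assert ResponseCategory.MODERATE not in cats

    def test_monotone_in_ic50(self):
        order = [
            ResponseCategory.RESPONDER,
            ResponseCategory.MODERATE,
            ResponseCategory.NON_RESPONDER,
        ]
        values = np.geomspace(0.01, 100, 40)
        ranks = [
            order.index(classify_response(est("d", v), self.TS).category)
            for v in values
        ]
        assert ranks == sorted(ranks)

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_threshold_derivation_is_scale_equivariant(self, k):
        values = [0.3, 0.8, 2.0, 5.0, 9.0, 20.0]
        base = derive_quartile_thresholds({"d": [est("d", v) for v in values]})["d"]
        scaled = derive_quartile_thresholds(
            {"d": [est("d", v * k) for v in values]}
        )["d"]
        assert scaled.lower == pytest.approx(base.lower * k, rel=1e-9)
        assert scaled.upper == pytest.approx(base.upper * k, rel=1e-9)
        for v in values:
            assert (
                classify_response(est("d", v * k), scaled).category
                is classify_response(est("d", v), base).category
            )


class TestROC:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 5.0, 9.0], [True, True, False, False])
        assert res.auc == 1.0
        assert res.operating_sensitivity == 1.0
        assert res.operating_specificity == 1.0

    def test_interleaved_labels(self):
        assert roc_auc([1, 2, 3, 4], [True, False, True, False]).auc == pytest.approx(0.75)

    def test_exchangeable_distributions_near_half(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=2000)
        labels = rng.random(2000) < 0.5
        assert roc_auc(scores, labels).auc == pytest.approx(0.5, abs=0.05)

    def test_single_class_is_undefined(self):
        with pytest.raises(UndefinedAUCError):
            roc_auc([1, 2, 3], [True, True, True])

    def test_rank_formulation_matches_pair_counting(self):
        # brute-force oracle over seeded instances with ties, n <= 50
        rng = np.random.default_rng(19)
        for _ in range(50):
            n = rng.integers(4, 51)
            scores = rng.integers(0, 10, size=n).astype(float)  # heavy ties
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            expected = auc_pair_counting(scores, labels)
            assert roc_auc(scores, labels).auc == pytest.approx(expected, abs=1e-12)

    def test_youden_cutoff_classifies_separated_cohort(self):
        scores = [0.1, 0.3, 0.5, 4.0, 8.0, 20.0]
        labels = [True, True, True, False, False, False]
        res = roc_auc(scores, labels)
        assert 0.5 < res.chosen_cutoff <= 4.0
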