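"""Derive cohort quartile thresholds and call per-drug responses.

A cohort of uncensored paclitaxel IC50s defines the 25th/75th-percentile
cutoffs; patients below the lower cutoff are Responders, between the two
Moderate, at or above the upper Non-Responders.  Censored (above-range)
estimates never enter the quantiles and are always Non-Responders.
"""

from spheroscreen import (
    IC50Censoring,
    IC50Estimate,
    classify_response,
    derive_quartile_thresholds,
)

cohort = [0.02, 0.05, 0.08, 0.6, 0.9, 1.5, 2.2, 4.0, 25.0, 60.0]
estimates = [IC50Estimate("paclitaxel", v, IC50Censoring.NONE) for v in cohort]
estimates.append(IC50Estimate("paclitaxel", None, IC50Censoring.ABOVE_RANGE))

thresholds = derive_quartile_thresholds({"paclitaxel": estimates})["paclitaxel"]
print(f"thresholds: lower={thresholds.lower:.3f} µM, upper={thresholds.upper:.3f} µM")

for est in estimates:
    call = classify_response(est, thresholds)
    label = f"{est.value:.3f} µM" if est.value is not None else est.censoring.value
    print(f"  IC50 {label:>12} -> {call.category.value}")
print("The three categories partition the cohort at its own quartiles; "
      "the censored curve is a Non-Responder by definition.")
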