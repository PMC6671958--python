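"""Progression-free survival comparison of predicted response groups.

Draws exponential PFS for two synthetic groups with true medians 21 and
8 months (administratively censored at 36 months), then estimates KM
medians, the Gehan-Breslow-Wilcoxon p-value and the Mantel-Haenszel
hazard ratio.  The estimates recover the generating medians and a hazard
ratio near 8/21 = 0.38.
"""

import math

import numpy as np

from spheroscreen import (
    PredictionGroup,
    SurvivalRecord,
    compare_groups,
)

rng = np.random.default_rng(1)


def draw(median, group, prefix, n=300):
    times = rng.exponential(median / math.log(2), n)
    return [
        SurvivalRecord(f"{prefix}{i}", min(t, 36.0), t <= 36.0, group)
        for i, t in enumerate(np.maximum(times, 0.05))
    ]


records = draw(21.0, PredictionGroup.PREDICTED_RESPONDER, "r") + draw(
    8.0, PredictionGroup.PREDICTED_NONRESPONDER, "n"
)
cmp = compare_groups(records)
med = cmp.median_by_group
print(f"median PFS, predicted responders:     "
      f"{med[PredictionGroup.PREDICTED_RESPONDER]:.1f} months")
print(f"median PFS, predicted non-responders: "
      f"{med[PredictionGroup.PREDICTED_NONRESPONDER]:.1f} months")
print(f"Gehan-Breslow-Wilcoxon p = {cmp.wilcoxon_p:.2e}")
hr = cmp.hazard_ratio
print(f"hazard ratio {hr.hazard_ratio:.3f} "
      f"(95% CI {hr.ci_lower:.3f} to {hr.ci_upper:.3f})")
print("A hazard ratio well below 1 means predicted responders progress "
      "later; the CI excluding 1 makes the prognostic separation significant.")
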