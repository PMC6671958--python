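"""Diagnostic accuracy of predictions against clinical outcomes.

Uses the adjuvant cohort's contingency counts (26 TP, 0 FP, 4 FN, 5 TN)
to compute accuracy, sensitivity and specificity with Wilson 95% CIs and
the two-sided Fisher exact p, then applies the exploratory pre-surgery
CA-125 < 60 U/mL disqualifier, which removes the four false negatives
and two true positives and leaves a perfectly concordant 29-patient
cohort.
"""

import pandas as pd

from spheroscreen import (
    ConfusionMatrix,
    apply_ca125_disqualifier,
    build_confusion,
    diagnostic_summary,
)

cm = ConfusionMatrix(tp=26, fp=0, fn=4, tn=5)
s = diagnostic_summary(cm)
print(f"accuracy    {s.accuracy:5.1f}%")
print(f"sensitivity {s.sensitivity:5.1f}%  (95% CI {s.sensitivity_ci[0]:.1f} to {s.sensitivity_ci[1]:.1f})")
print(f"specificity {s.specificity:5.1f}%  (95% CI {s.specificity_ci[0]:.1f} to {s.specificity_ci[1]:.1f})")
print(f"Fisher p    {s.fisher_p:.4f}")
print(f"diagnostic odds ratio {s.dor:.1f} (Haldane-corrected: {s.dor_corrected})")

rows = []
rows += [("TPhi%02d" % i, True, True, 150.0 + 10 * i) for i in range(24)]
rows += [("TPlo01", True, True, 15.0), ("TPlo02", True, True, 42.0)]
rows += [("FN%02d" % i, False, True, ca) for i, ca in enumerate((18, 35, 47, 58))]
rows += [("TN%02d" % i, False, False, ca)
         for i, ca in enumerate((151.4, 500, 1200, 4000, 9796))]
cohort = pd.DataFrame(rows, columns=["patient_id", "predicted", "responder",
                                     "ca125_presurgery_u_ml"])

retained, removed = apply_ca125_disqualifier(cohort, cutoff=60.0)
cm_f = build_confusion(
    dict(zip(retained["patient_id"], retained["predicted"])),
    dict(zip(retained["patient_id"], retained["responder"])),
)
s_f = diagnostic_summary(cm_f)
print(f"\nafter CA-125 < 60 disqualifier: {len(retained)} patients "
      f"(removed {sorted(removed['cell'])})")
print(f"accuracy {s_f.accuracy:.1f}%  DOR {s_f.dor:.0f}")
print("Filtering on a biomarker measured before the assay removes the "
      "false-negative subgroup entirely.")
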