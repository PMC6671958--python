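# Methods

## Assay model

Each well of a 3D-spheroid microplate reports relative luminescence
(RLU) proportional to viable-cell ATP. Viability at concentration `c`
(µM) follows the falling four-parameter logistic

    V(c) = bottom + (top − bottom) / (1 + (c / IC50)^hill),  hill > 0,

where `top` is the vehicle-normalized plateau (≈1), `bottom` the
residual fraction at full effect, and `IC50` the dose of half-maximal
effect. Drugs are dosed on an 8-point log-spaced grid from 0.005 to
100 µM with seven replicate wells per dose; the grid size is
configurable (the dosing window is the assay's published design, the
point count a package default).

**QC gates** (per plate, all configurable): vehicle mean RLU ≥ 1000
synthetic units, vehicle/blank dynamic range ≥ 3, ≥ 7 replicates at
every dose. A plate missing vehicle or blank wells is malformed rather
than failed; QC failures are reported per plate and never abort a cohort
run.

**Normalization** divides each drug-well RLU by the plate's vehicle mean
and averages replicates per dose. Fractions above 1 (stimulation) are
retained: clipping would bias the fitted top plateau downward.

**Fitting** runs bounded least squares on log10 dose with multi-start
initialization — the log-IC50 start is seeded at every tested dose plus
the grid midpoint, and the best residual sum of squares wins. Bounds:
top and bottom in [0, 1.5], hill in [0.1, 10], IC50 in [1e−5, 1e5] µM so
off-grid optima remain representable. Convergence tolerances are tight
(xtol = ftol = 1e−12) so noiseless curves are recovered to ~1e−8
relative. A curve whose observed viability range is below 0.1 is
declared unidentifiable (`converged=False`) rather than assigned an
arbitrary interior IC50; this is what a flat "no response" curve
produces.

**Censoring**: a failed fit is `fit_failed`; a fitted IC50 above the top
tested dose is `above_range` — both are Non-Responders downstream. An
IC50 below the lowest dose (`below_range`) is flagged as anomalous and
refused at classification time rather than silently mapped to Responder,
because that configuration is not expected to occur in practice.

## Response calling

Cutoffs are cohort-relative: the 25th and 75th percentiles of a drug's
uncensored IC50s (exact quantiles with linear interpolation — the
reproducible stand-in for manually chosen "approximate" quartiles; the
levels are configurable). Ternary calls use half-open intervals:
IC50 < lower → Responder, [lower, upper) → Moderate, ≥ upper →
Non-Responder; the boundary convention is fixed and documented because
ties must land somewhere deterministic. Censored values are excluded
from quantile derivation (quantiles of censored data are ill-defined)
but always called Non-Responder.

Carboplatin is called binary. The default cutoff is the cohort median;
when binary clinical labels are available the Youden-optimal ROC cutoff
can be used instead, with the AUC computed as the Mann–Whitney rank
statistic (low IC50 = positive, ties one half).

## Regimen prediction and clinical outcomes

A patient is a predicted regimen Responder iff at least one drug both
received and tested carries a Responder call; Moderate counts as
non-support for every drug (the conservative generalization of the
stated paclitaxel rule). Drugs received but never tested are logged and
ignored.

Adjuvant outcome at six months post-chemotherapy: progression on
imaging at or before the evaluation point → non-responder (refractory if
within three months of treatment start); otherwise a non-progressing
imaging assessment (NED or stable) outweighs CA-125; with no imaging in
the window, CA-125 ≤ 35 U/mL → responder. The 35 U/mL point mass is
assigned to responder — the rule text defines only "below" and "above",
so the boundary needed a documented owner. The evaluation clock starts
at chemotherapy completion.

Neoadjuvant outcome is RECIST 1.1 on target-lesion diameter sums:
CR = all lesions resolved, no new lesions; PD = new lesions or ≥ +20%
with ≥ 5 mm absolute increase (the absolute guard is part of RECIST 1.1
and is enforced even though small sums rarely occur here); PR = ≤ −30%;
SD otherwise. CR/PR map to clinical response.

## Concordance statistics

Wilson score intervals (no continuity correction) are used for
sensitivity and specificity — this interval reproduces the printed
adjuvant and combined bounds digit for digit, and behaves at observed
proportions of 0 and 1. Fisher's exact test is the two-sided sum of
hypergeometric point probabilities no larger than the observed table's.
The diagnostic odds ratio (TP·TN)/(FP·FN) receives the Haldane–Anscombe
+0.5 on all cells whenever any cell is zero, and carries a correction
flag; DOR is reported descriptively only, since zero-cell odds ratios
have no canonical point estimate. The CA-125 disqualifier retains
patients with pre-surgery CA-125 ≥ 60 U/mL; rows with missing CA-125 are
warned about and retained with a skip flag — absent data never silently
removes a patient.

## Survival

Kaplan–Meier product-limit curves per predicted group, with the median
defined as the first time the curve reaches 0.5 (within 1e−9, so an
exact product-limit value of one half counts as crossed). Group
comparison uses the Gehan–Breslow generalized Wilcoxon (weight = number
at risk, emphasizing early separation), matching the convention used for
PFS plots of this kind. The hazard ratio is Mantel–Haenszel,
(O₁/E₁)/(O₂/E₂) over distinct event times, with a log-scale normal CI
using SE = √(1/E₁ + 1/E₂); it is hand-coded because the installed
survival library exposes Cox regression, not the contingency-style O/E
ratio. The O/E ratio mildly attenuates extreme hazard ratios toward 1
(a known property); parameter-recovery tests budget for this. The PFS
clock starts at surgery.

## Synthetic cohort generator

The generator emulates the study's two arms (default 44 patients,
35 adjuvant / 9 neoadjuvant) over the six-drug panel (carboplatin,
paclitaxel, doxorubicin, topotecan, gemcitabine, olaparib).

*Assay side.* Each patient-drug pair draws a true 4PL curve: IC50 from a
per-drug mixture over sensitivity classes with log-uniform, gap-separated
supports (ternary weights 0.25/0.50/0.25 with supports 0.01–0.1,
0.5–5 and 20–300 µM; carboplatin binary 0.5/0.5 with supports 0.1–2 and
20–90 µM), hill in [0.8, 2.5], bottom in [0, 0.15]. Non-responder IC50s
above 100 µM produce genuinely censored curves. Well RLU is
`vehicle_scale · V(c) · (1 + ε)` with multiplicative Gaussian noise of
CV 0.10 (typical luminescence plate-reader noise), truncated at zero;
plates carry 14 vehicle, 7 blank and 14 kill-control wells.

*Ground truth categories are cohort-relative by design.* The response
categories of this assay are defined by cohort quartiles, so a
generative "true class" independent of the cohort would be ill-posed.
The generator therefore applies the same quantile rule to the true IC50
vector that the pipeline applies to fitted IC50s. Consequences worth
stating plainly: the noiseless round trip is an exact test of
measurement (fitting) error, not of an external class boundary; and the
gap-separated supports guarantee no true IC50 sits within fit precision
of a threshold, so noiseless category recovery is exact. Carboplatin's
resistant support stays inside the tested window so the binary median
cutoff splits the cohort at the mixture weight; ternary drugs keep a
censored tail, which shifts the uncensored quantiles slightly, so their
empirical responder fractions sit a few percent below the nominal 0.25
at large n.

*Clinical side.* A patient is regimen-sensitive iff any received drug
(default regimen: carboplatin + paclitaxel) is a true Responder.
Clinical response is Bernoulli with linked rates — 1.0 for sensitive
and 0.42 for resistant patients, the study's observed contrast. A
low-CA-125 subgroup (fraction 6/35 of adjuvant patients) draws
pre-surgery CA-125 uniformly in 15–59 U/mL and responds clinically
regardless of assay class; this models the observed false-negative
mechanism as an outcome-side override, which is what lets the CA-125
disqualifier restore perfect concordance on synthetic data. Everyone
else draws CA-125 log-uniformly in 100–20000 U/mL. Follow-up series are
generated consistent with the drawn response (responders: NED imaging
and CA-125 < 35 at the six-month evaluation; non-responders: progression
— refractory with probability 0.6, matching 3 of 5 in the reference
cohort); chemotherapy lasts 5 months. Neoadjuvant lesion sums start
uniform in 30–150 mm with changes drawn inside the appropriate RECIST
window per response class. PFS is exponential with class medians 21 and
8 months, administratively censored at 36 months.

*What the generator does not emulate:* spatial plate effects (edge
wells), inter-plate drift, correlated sensitivity across drugs within a
patient, non-exponential PFS shapes, CA-125 kinetics between visits, and
assay failures other than the configured QC gates. Pipeline tests
passing on synthetic data therefore validate the analytics, not the
assay's biological accuracy on real tissue.

## Problem sizes and numerical choices

The test suite uses cohorts of 10–60 patients for pipeline round trips,
2000–4000 truth-only patients for distributional checks, and 500 per arm
for survival recovery — sizes at which binomial and KM error bands are
comfortably inside the asserted tolerances. The acceptance script uses a
44-patient noiseless cohort and 500 per arm for survival. Fit
determinism comes from fixed multi-start order; generator determinism
from a single `numpy` Generator seeded once and consumed in fixed order,
so equal seeds give bitwise-equal cohorts.

## Known limitations

- The neoadjuvant-subtable interval bounds printed in some reports of
  this assay (e.g. 99.3 upper for 6/7, 17.8 lower for 2/2) match neither
  Wilson, Clopper–Pearson, nor continuity-corrected Wilson; this package
  reports Wilson for every proportion rather than mixing interval
  methods per subtable.
- The Mantel–Haenszel hazard ratio is not a consistent estimator far
  from 1; for publication-grade hazard ratios a Cox model should be
  fitted alongside.
- Quartile cutoffs from small cohorts (< ~20 uncensored IC50s) are
  noisy; `derive_quartile_thresholds` enforces only the minimal n = 4
  and leaves cohort-size judgement to the analyst.
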