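# Methods

## Risk models

Each model sums integer component scores and bins the total:

- `demicco3`: age + size + mitoses; low 0–2, intermediate 3–4, high 5–6.
- `demicco4`: adds the necrosis point; low 0–3, intermediate 4–5, high 6–7.
- `modified3` / `modified4`: the Ki-67 LI score replaces the mitotic score;
  category cut-offs unchanged.

All bins are half-open and closed on the higher-score side: "≥ 55 years",
"≥ 15 cm", "≥ 10%" are inclusive, and ranges written like "0–4.9 cm" are
read as [0, 5) — so 4.95 cm scores 0. The published mitotic bins
(0 / 0.5–1.5 / ≥ 2 per mm²) do not tile the line; any nonzero rate below
2/mm² scores 1 here, which keeps the printed anchors, accepts fractional
rates, and preserves monotonicity of the total in every raw covariate
(property-tested). Missing covariates are rejected rather than imputed: a
record must be complete for the requested model.

`ScoreBins` externalizes every edge and category cut-off, so the four
models are configuration; `enumerate_score_space` walks the full component
product space (24 or 48 combinations) and is the oracle that the category
bins are exhaustive and mutually exclusive over attainable totals (0–6 and
0–7).

## Survival statistics

Metastasis-free survival (MFS) is time from resection/biopsy to distant
metastasis. Patients without metastasis — including deaths without
documented metastasis — are censored at last follow-up; competing-risks
treatment of death is out of scope, and MFS is the only endpoint.

The Kaplan–Meier estimator, Greenwood variance and log-rank test are
implemented from first principles (they are the package's core, not a
wrapped dependency); `lifelines` is used purely as an independent oracle in
the tests, where both S(t) and the log-rank statistic agree to better than
1e-9 on randomized censored fixtures.

Numerical conventions:

- Ties between an event and a censoring at the same time are resolved
  events first (the censored subject remains in that risk set).
- 95% confidence bands use Greenwood variance on the complementary log-log
  scale (the band is range-respecting and behaves well near S = 1); a plain
  linear band clipped to [0, 1] is available via `ci_method="linear"`. The
  band is undefined at S = 0 and S = 1.
- "5 years" is exactly 60.0 months. `survival_at` evaluates the step
  function right-continuously; if no event occurred at or before the query
  time it returns S = 1 with the CI flagged undefined, which the report
  layer renders as the footnote "95% CI was not calculated because of no
  events until 5 years" instead of a degenerate (100, 100) band.
- The log-rank test supports k ≥ 2 groups via the (k−1)-dimensional
  quadratic form with hypergeometric covariance (times with a single
  subject at risk contribute no variance); the two-group case reduces to
  (O−E)²/V. Zero events overall, or fewer than two groups, are errors: the
  statistic is undefined there, and the report layer shows "NA" for such
  stratifications. Survival times must be strictly positive; a metastasis
  recorded at time 0 is rejected as a data error.

Monte-Carlo checks: under a two-arm exponential null (50 per arm, uniform
administrative censoring on [1, 250] months, 5000 replicates) the log-rank
rejection rate at α = 0.05 stays within three binomial standard errors of
0.05; with the simulator's dichotomized hazard ratio at 5 and n = 400 the
test rejects in essentially every replicate.

## Ki-67 quantification

The quantifier starts where image analysis ends: per-field counts of
Ki-67-positive and -negative tumor nuclei (nuclear staining only). The
labeling index of a field is 100·positive/(positive+negative); the hot spot
is the field with maximal LI among fields with at least `min_nuclei`
counted nuclei (default 500 — no threshold is published, and 500 nuclei cap
the binomial standard error of a 10% LI near 1.3 percentage points); ties
break deterministically by field identifier. The hot-spot LI then feeds the
0/1/2 Ki-67 score. Nucleus detection, stain deconvolution and anything
pixel-level are out of scope.

## Synthetic cohorts

No per-patient data accompany the study this package models, so the
simulator is the test bed for every downstream stage. It emulates the
published cohort's *marginal* structure: each covariate's score category is
drawn independently from the published proportions (n = 43: 24/43 aged
≥ 55, 24/10/3/6 across the size bins, 34/4/5 across the mitotic bins,
15/24/4 across the Ki-67 bins, 40/3 for necrosis, 21/43 male, 10/12/6/15
across locations, 2/43 dedifferentiated), then a raw value uniformly within
the drawn category's bin. Open-ended bins are truncated at clinically
plausible bounds: age 95 (lower bound 18 — an adult cohort), size 25 cm
(lower bound 1 cm), mitoses 10/mm², Ki-67 80%. Raw values are rounded to
reporting precision *within* the bin (rounding is clamped so a boundary
draw cannot cross into the neighbouring score category).

Survival depends on the covariates only through the dichotomized group of a
chosen model (default `modified3`): metastasis times are exponential with
per-month hazards `hazard_low` = 0.0005 and `hazard_high` = 0.005 by
default — five-year MFS of about 97% vs 74%, mirroring the qualitative
contrast of the real cohort (no low-risk events within five years;
intermediate/high around 74%) — censored administratively at a follow-up
drawn uniformly on [1, 250] months (the published follow-up range).
Identical configs yield identical cohorts byte-for-byte in CSV form.

What the simulator does **not** emulate, and hence what passing tests do
not show about real data: covariates are independent across variables
(real tumors correlate size, proliferation and necrosis — a joint structure
the published marginals cannot identify), hazards are proportional and
exponential rather than covariate-rich, follow-up is uniform rather than
right-skewed as in the study (median 43, mean 63 months), and no
measurement error links the Ki-67 field counts to the cohort-level LI.
Tests passing on these cohorts validate the *pipeline arithmetic and the
estimators' statistical properties*, not the clinical performance of the
models.

## Reporting conventions

Percentages are rounded half-up to one decimal and always recompute exactly
from the stored counts. P-values display to three decimals with very small
values floored at "<0.001" (the source table's "0.000" convention is
ambiguous, so the floor is explicit). A stratum with zero events before 60
months reports 100% MFS with the CI replaced by the footnote marker; a
block with fewer than two populated levels, or no events at all, reports
the log-rank p as not computable ("NA"). The report is emitted both as a
tidy CSV and as a Markdown table.

## Problem sizes

The test suite and acceptance script use: exhaustive 24/48-row score
spaces; 200 randomized fixtures (n ≤ 200) for oracle equivalence; 5000
replicates for null calibration; 500 (tests) / 300 (acceptance script)
replicates of n = 400 cohorts for power and size; 50 000 records for
marginal-recovery goodness of fit. These sizes give Monte-Carlo standard
errors small enough for the stated three-standard-error bands while keeping
a full run in well under half an hour on one CPU.
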