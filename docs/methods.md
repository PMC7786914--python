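# Methods

This note records the statistical model the package implements, the
choices that were genuinely open, the numerical conventions that are
pinned for reproducibility, and what the synthetic cohort does and does
not emulate.

## Data model and time conventions

A cohort is a subject table (exit day, event indicator, admission
covariates) and a long-format measurement table (subject, marker, day,
value). Admission is day 1; all times are integer days. Death in the ICU
on day *d* is the event at *t* = *d*; live discharge is right-censoring
at the exit day. Week *k* is days 7(*k*−1)+1 … 7*k*, so the weekly
cumulative/dynamic horizons are τ_k = 7*k*. Validation is strict: an
observation recorded after a subject's exit day, an orphan measurement,
or a negative/non-finite lab value is an error, never a silent drop.

## Marker preprocessing

1. **Daily worst.** Multiple same-day measurements collapse to the
   clinically poorest one: maximum for higher-is-worse markers, minimum
   for the platelet count. Idempotent by construction.
2. **Orientation.** Lower-is-worse markers are negated so a larger
   oriented value always means worse. Negation is strictly
   order-reversing, so every rank statistic downstream is unchanged in
   magnitude and only flipped in direction; a second orientation of an
   already-oriented series is refused rather than silently undone.
3. **Baseline.** The admission value is the day-1 observation, falling
   back to day 2 when the first labs were timestamped past midnight.
   Later first observations signal a missing baseline; those subjects are
   excluded from baseline-mode analyses of that marker (and counted).
4. **LOCF.** The updated value at day *d* is the last observed oriented
   value at or before *d* — piecewise constant, right-continuous, no
   interpolation or smoothing. Lookback is unlimited by default; a
   maximum-staleness override is available for sensitivity analyses.

Subjects with no measurements of a marker are excluded from that marker's
analyses; every exclusion is counted in the run log.

## Incident/dynamic estimation

One risk set per distinct death day: same-day deaths pool as cases
against the common controls (day resolution makes their order
unknowable). The AUC at each risk set is the exact Mann–Whitney rank
statistic with ties worth one half, computed through midranks
(O(n log n), identical to exhaustive pair counting). Weekly summaries are
event-count-weighted means of the event-day AUCs within the week; weeks
without events are omitted.

The concordance index integrates AUC(t) over event days up to a
truncation day τ (default 56, the end of week 8, after which events are
sparse) with weights proportional to 2·ΔF(t)·S(t) from the Kaplan–Meier
curve of the death time — the standard incident/dynamic comparability
weight — renormalized over the included days so the c-index is a convex
combination of the AUC points. The weighted mean divides the dot product
by the weight sum rather than pre-normalizing the weights, which keeps
degenerate cases (all AUCs equal) exact in floating point. The
Kaplan–Meier curve itself comes from lifelines' product-limit fitter.

## Cumulative/dynamic estimation

Week *k* eligibility is "still in the ICU at the week's start"
(exit day > 7(*k*−1)). Positives are eligible subjects dying within the
week; *all* other eligible subjects are negatives, including those
discharged alive during the week — this is what makes the week-1 group
sizes sum to the full cohort, and it makes the weekly positive groups a
partition of all deaths. No inverse-probability-of-censoring weighting is
applied: the estimand is the plain two-group comparison on the weekly
subset. The updated value entering week *k* is the LOCF value at the
week's *first* day, so the comparison remains a prediction of the coming
week; using within-week or day-of-event values would leak
outcome-adjacent information. The alternative ("last value before exit")
is exposed as a configuration flag for sensitivity analysis.

The ROC curve sweeps thresholds over the observed values, calling
"worse or equal" positive; its trapezoidal area equals the pairwise rank
AUC exactly (diagonal tie segments reproduce the ½ convention).

## Bootstrap

The resampling unit is the subject; each draw carries the subject's whole
measurement history, preserving within-subject correlation. Intervals are
equal-tailed percentile intervals; the percentile rule is linear
interpolation between order statistics (numpy's default), the same rule
used for the descriptive quartiles. Resamples where a statistic is
undefined (a resampled cohort may lose all of a week's deaths) are
dropped and counted, never imputed; a scalar statistic undefined on more
than half the resamples is an error. In the pipeline's joint bootstrap,
sparse late weeks routinely go undefined under resampling; such
components keep their point estimate and report NaN bounds instead of
aborting the run. The pipeline bootstraps rows of precomputed per-subject
panels (baseline value, LOCF row, exit day, event flag) rather than
rebuilding cohort objects — statistically identical, since every panel
row is a pure per-subject feature, and an order of magnitude faster; all
statistics share the same resamples.

## Synthetic cohort generator

The generator's defaults are the study conditions the pipeline targets:
2,259 subjects, ~21% ICU mortality (intercept calibrated by root-finding
on the logistic link), median stay ~14 days (survivors log-normal, median
15 d; non-survivors Weibull, median 12 d), admission medians near age 48,
TBSA ~28%, inhalation ~52%. Severity is a standardized linear combination
of TBSA, age, inhalation and noise.

Severity determines **whether** a subject dies; the Weibull alone
determines **when**. This decoupling is deliberate: if sicker subjects
also died systematically earlier, the survivors of the first weeks would
be selected mild cases, and no severity-driven marker could discriminate
in the late weeks — the generator could then never produce a
late-strengthening marker, which is one of the trajectory shapes the
estimators must be exercised against. The cost is a known non-realism
(in real ICUs severity and death timing are correlated), and one visible
consequence: weekly death counts decline from week 1 instead of peaking
in week 2 as the emulated cohort's counts do.

Marker values follow `loc + between_sd·zᵢ + s·effect·severityᵢ·profile(d)
+ noise`, with `s` the worse direction and `profile` one of:

* `early` — exp(−(d−1)/10): admission-shock markers (lactate, WBC);
  discrimination strongest in week 1, decaying after.
* `late` — 1 − exp(−(d−1)/14): cumulative organ-failure markers
  (platelet, creatinine, bilirubin); zero signal at admission, growing
  over the stay. A consequence worth knowing: the *baseline* value of a
  late marker is pure noise, so its baseline-mode AUC sits at chance at
  every week — the late rise is expressed, and tested, through the
  updated mode.
* `constant` — uniformly informative (PT).

Day 1 is always recorded (admission labs); later days are thinned by a
per-marker measurement probability (0.9–0.95). Values are clipped at
zero. Two diagnostic overrides exist: a *perfect* marker (a strictly
monotone function of the exit day, oriented worse for earlier exits) and
a *null* marker (no severity term).

The perfect marker forces every incident/dynamic AUC and the c-index to
exactly 1.0 on any cohort. For the weekly cumulative/dynamic comparison
it is perfect only when live discharges do not interleave with deaths
inside a week: a subject discharged alive on day 3 is a *negative* whose
exit-day rank beats a positive dying on day 6, and no function of the
exit day can repair that — the discharged subject's counterfactual death
day is simply unknown. Limit-case tests of the C/D estimator therefore
push survivor discharges past day 56.

What passing tests on these cohorts does **not** show: robustness to
informative observation schedules (real labs are ordered *because*
patients deteriorate), to measurement error correlated with outcome, to
physiologic episode structure (sepsis, AKI), or to the severity–timing
correlation discussed above. The generator provides controllable
discrimination structure, not patient physiology.

## Descriptive table

Continuous variables: median [25th;75th percentile] with the two-sample
rank-sum (Mann–Whitney) test — the paired signed-rank test is not
applicable to independent survivor/non-survivor groups. Categorical
variables: count (percent) with the chi-square test, no continuity
correction by default (flag available). Marker rows use raw (unoriented)
admission values. Quartiles use the same linear-interpolation rule as the
bootstrap percentiles. Missing values are reported in an explicit column,
never silently dropped.

## Problem sizes used in the shipped checks

The test-suite exercises the estimators at cohort sizes 25–6,000 and the
full pipeline at 120–2,259 subjects with 4–500 bootstrap resamples; the
reproduction script runs the complete pipeline at the default 2,259
subjects with 500 resamples, the binormal recovery at 2,000+2,000 values
over 10 seeds, and the null-marker limit at 3,000 subjects over 5 seeds.
These sizes were chosen so each check is decisive for the property it
verifies while the whole suite stays desk-scale.

## Known limitations

* No IPCW or model-based (semiparametric) time-dependent sensitivity:
  both approaches are the plain rank-based estimators described above.
* No competing-risks treatment of discharge (it is censoring by the
  outcome definition, but early discharge is plausibly informative).
* The week-k updated value is a single day's carry-forward; no
  within-week aggregation is offered.
* Severity-score covariates (ABSI, APACHE, and similar) are out of scope.
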