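# tvroc

Time-varying discrimination of longitudinal ICU biomarkers under
right-censoring: incident/dynamic and cumulative/dynamic time-dependent
ROC/AUC, a Kaplan–Meier-weighted concordance index, and subject-level
bootstrap percentile confidence intervals — with a synthetic burn-ICU
cohort generator so every stage is testable without access to a clinical
database.

## The problem

Intensive-care biomarkers (white cell count, platelet count, creatinine,
lactate, total bilirubin, prothrombin time) are usually evaluated as
admission snapshots, but they are re-measured daily and the patient's
state drifts. The question this package answers quantitatively: **how well
does a marker separate the patients about to die from those who will
survive, at each point of the stay — and how much does routinely updating
the marker improve on its admission value?**

Patients leave the cohort in two ways: death in the ICU (the event) or
live discharge (right-censoring). All times are integer days since
admission (admission = day 1); week *k* spans days 7(*k*−1)+1 … 7*k*.

## The statistics

Let *T*ᵢ be the exit day, δᵢ the death indicator, and *M*ᵢ(*t*) the
oriented marker process (oriented so larger = worse; daily worst value,
carried forward between measurements).

**Incident/dynamic (I/D) AUC.** At each death day *t*, cases are the
subjects with *T*ᵢ = *t*, δᵢ = 1 and controls are those with *T*ᵢ > *t*.
The AUC is the nonparametric rank statistic

  AUC(t) = (1 / n₁n₀) Σ over case–control pairs [ 1{case > control} + ½·1{tie} ],

evaluated either on the fixed admission value ("baseline") or the value
carried forward to *t* ("updated").

**Concordance index.** The curve is summarized over a horizon τ (default
day 56) as

  c = Σ_{t ≤ τ} w(t) · AUC(t),  w(t) ∝ 2·ΔF(t)·S(t),

with S the Kaplan–Meier survival curve of the death time and ΔF its mass
at *t*; the weights are normalized to sum to one, making c a convex
combination of the AUC points.

**Cumulative/dynamic (C/D) weekly AUC.** For each week *k*, among the
subjects still in the ICU at the week's start, positives are the deaths of
days 7(*k*−1)+1 … 7*k* and negatives are everyone else (including live
discharges within the week); the same rank AUC compares marker values
taken at the week's first day.

**Uncertainty.** Subjects (with all their series) are resampled with
replacement; 95% intervals are empirical percentiles of the resampled
statistics (500 resamples by default, deterministic per seed).

## Worked example

```python
from tvroc import SimulationConfig, analyze_id, generate

cohort = generate(SimulationConfig(n_subjects=2259, seed=1))
for marker in ("platelet", "lactate", "PT"):
    base = analyze_id(cohort, marker, "baseline")
    upd = analyze_id(cohort, marker, "updated")
    print(f"{marker:10s} c-index baseline {base.cindex:.3f}  updated {upd.cindex:.3f}")
```

prints

```
platelet   c-index baseline 0.490  updated 0.643
lactate    c-index baseline 0.727  updated 0.618
PT         c-index baseline 0.712  updated 0.724
```

On this synthetic cohort the platelet count is generated as a
*late-divergence* marker: its admission value carries essentially no
signal (baseline c ≈ 0.49, chance level) while re-measuring it raises the
c-index to 0.64 — re-measurement is what makes it useful. Lactate is an
*admission-shock* marker: strong at admission (0.73) and decaying as the
early signal goes stale. The weekly cumulative/dynamic view
(`examples/03_cumulative_dynamic.py`) shows the same story resolved in
time: updated lactate AUC falls 0.73 → 0.37 from week 1 to week 8 while
updated platelet AUC climbs 0.46 → 0.84 by week 7.

The `examples/` directory has one short script per capability (cohort
simulation, I/D analysis, C/D analysis, bootstrap, full pipeline,
descriptive table); each prints its numbers with a line on what they mean.

A thin CLI wraps the same library calls:

```bash
tvroc simulate --n 2259 --seed 1 --out cohort/
tvroc analyze --subjects cohort/subjects.csv --measurements cohort/measurements.csv \
      --out results/ --seed 1 --n-boot 500
tvroc summarize --subjects cohort/subjects.csv --measurements cohort/measurements.csv \
      --out summary.csv
```

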