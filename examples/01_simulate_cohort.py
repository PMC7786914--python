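"""Generate a synthetic burn-ICU cohort and look at its shape.

The generator emulates the study conditions the pipeline was built for:
~21% ICU mortality, median stay around two weeks, six longitudinal
markers recorded daily (worst value of the day) until death or discharge.
"""

from tvroc import SimulationConfig, generate, weekly_counts

cohort = generate(SimulationConfig(n_subjects=2259, seed=1))
subj = cohort.subjects

print(f"subjects            {cohort.n_subjects}")
print(f"measurement rows    {cohort.n_observations}")
print(f"ICU mortality       {100 * subj['event'].mean():.1f}%")
print(f"median stay         {subj['exit_day'].median():.0f} days")
print(f"median age          {subj['age'].median():.1f} years")
print(f"median TBSA         {subj['tbsa'].median():.1f}%")

print("\nweekly case/control allocation (cumulative/dynamic):")
for week, n_pos, n_neg in weekly_counts(cohort):
    print(f"  week {week}: {n_pos:4d} deaths, {n_neg:5d} negatives")

# Each week's deaths are counted once and only once: the positive groups
# partition all deaths occurring up to day 56.
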