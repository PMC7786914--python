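"""Descriptive survivor vs non-survivor comparison.

Continuous rows: median [IQR] with the two-sample rank-sum test;
categorical rows: count (percent) with the chi-square test. Marker rows
use the raw admission (day 1-2) values.
"""

from tvroc import SimulationConfig, generate, summarize

cohort = generate(SimulationConfig(n_subjects=2259, seed=1))
table = summarize(cohort, variables=("age", "tbsa", "inhalation", "lactate", "platelet"))
print(table.to_string(index=False))
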