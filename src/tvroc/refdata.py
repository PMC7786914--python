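"""Published summary counts of the severe-burns ICU cohort that the synthetic
generator emulates.

The original clinical database is not deposited; what is public are the
descriptive tables of the study cohort: group sizes, the printed overall
mortality, and the weekly survivor / non-survivor counts used by the
cumulative/dynamic weekly analysis. They serve two roles here:

* calibration targets for :mod:`tvroc.simulate` defaults, and
* inputs to simple arithmetic identities (mortality = deaths / total; the
  weekly death counts partition the deaths) that the test-suite and the
  reproduction script recompute.
"""

from __future__ import annotations

#: Cohort split printed in the descriptive table.
SURVIVORS_N = 1786
NON_SURVIVORS_N = 473

#: Overall mortality as printed (percent, one decimal).
PRINTED_MORTALITY_PCT = 20.9

#: Printed total cohort size.
PRINTED_TOTAL_N = 2259

#: Weekly counts entering the cumulative/dynamic analysis, weeks 1..8.
#: Non-survivors are deaths within the week; survivors are the remaining
#: eligible (at-risk at week start) subjects, including those discharged
#: alive during the week.
WEEKLY_NON_SURVIVORS = (126, 158, 69, 49, 30, 15, 12, 14)
WEEKLY_SURVIVORS = (2133, 1384, 1014, 781, 591, 449, 322, 235)

#: Medians the generator's defaults aim at.
MEDIAN_AGE_YEARS = 48.0
MEDIAN_TBSA_PCT = 24.0
MEDIAN_LOS_DAYS = 14.0
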