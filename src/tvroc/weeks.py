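"""Week/day conventions shared across the pipeline.

Admission day is day 1; week ``k`` spans days ``7(k-1)+1 .. 7k``, so the
fixed cumulative/dynamic horizons sit at the end of each week,
``tau_k = 7k``. The default truncation for the concordance index is the
end of week 8 (day 56), after which events are sparse.
"""

from __future__ import annotations

N_WEEKS = 8
DEFAULT_TAU_DAYS = 7 * N_WEEKS


def week_of_day(day: int) -> int:
    """Week index (1-based) containing ``day``."""
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    return (day - 1) // 7 + 1


def week_start(week: int) -> int:
    """First day of ``week``."""
    return 7 * (week - 1) + 1


def week_end(week: int) -> int:
    """Last day of ``week`` (the C/D horizon tau_k)."""
    return 7 * week
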