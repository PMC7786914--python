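"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tvroc.cohort import Cohort, MarkerSeries, SubjectRecord
from tvroc.simulate import SimulationConfig, generate

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def pairwise_auc_oracle(cases, controls) -> float:
    """Exhaustive pair-counting AUC: 1 per winning pair, 0.5 per tie.

    Deliberately brute force; the independent check for the rank-based
    implementation.
    """
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def km_oracle(exits, events) -> dict[int, float]:
    """Hand product-limit estimate: S(t) after the deaths at each death day."""
    surv = 1.0
    out = {}
    for t in sorted({e for e, d in zip(exits, events) if d == 1}):
        at_risk = sum(1 for e in exits if e >= t)
        deaths = sum(1 for e, d in zip(exits, events) if d == 1 and e == t)
        surv *= 1.0 - deaths / at_risk
        out[t] = surv
    return out


def subject(sid: str, exit_day: int, event: int, **kw) -> SubjectRecord:
    defaults = dict(age=48.0, sex=1, tbsa=25.0, inhalation=0, burn_type="flame")
    defaults.update(kw)
    return SubjectRecord(sid, exit_day, event, **defaults)


def constant_series(sid: str, marker: str, value: float, days) -> MarkerSeries:
    return MarkerSeries(sid, marker, tuple((int(d), float(value)) for d in days))


@pytest.fixture
def three_subject_cohort() -> Cohort:
    """A deaths day 3, B day 5, C discharged day 7; constant marker A>B>C."""
    subjects = [subject("A", 3, 1), subject("B", 5, 1), subject("C", 7, 0)]
    series = [
        constant_series("A", "lactate", 5.0, range(1, 4)),
        constant_series("B", "lactate", 2.0, range(1, 6)),
        constant_series("C", "lactate", 1.0, range(1, 8)),
    ]
    return Cohort.from_records(subjects, series)


@pytest.fixture
def km_worked_cohort() -> Cohort:
    """Deaths on days 1 and 3, censored exits on days 2 and 4."""
    return Cohort.from_records(
        [
            subject("d1", 1, 1),
            subject("c2", 2, 0),
            subject("d3", 3, 1),
            subject("c4", 4, 0),
        ]
    )


@pytest.fixture(scope="session")
def medium_cohort() -> Cohort:
    """Default-parameter synthetic cohort, small enough for fast tests."""
    return generate(SimulationConfig(n_subjects=400, seed=11))


def random_instance(rng: np.random.Generator, max_n: int = 50):
    """Random case/control values with ties injected (small integer grid)."""
    n1 = int(rng.integers(1, max_n + 1))
    n0 = int(rng.integers(1, max_n + 1))
    grid = rng.integers(0, 12, size=n1 + n0).astype(float) / 2.0
    return grid[:n1], grid[n1:]
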