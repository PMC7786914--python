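"""Daily-worst aggregation, orientation, baseline and LOCF evaluation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from tvroc.cohort import MarkerConfig, MarkerSeries, default_marker_configs
from tvroc.preprocess import (
    OrientedDailySeries,
    aggregate_daily_worst,
    baseline_value,
    marker_at,
    marker_panel,
    orient,
)
from tvroc.simulate import SimulationConfig, generate

CFG = default_marker_configs()


def series(marker: str, obs) -> MarkerSeries:
    return MarkerSeries("p", marker, tuple((int(d), float(v)) for d, v in obs))


class TestAggregateDailyWorst:
    def test_platelet_keeps_daily_minimum(self):
        s = series("platelet", [(2, 200), (2, 150), (2, 180)])
        out = aggregate_daily_worst(s, CFG["platelet"])
        assert out.observations == ((2, 150.0),)

    def test_lactate_keeps_daily_maximum(self):
        s = series("lactate", [(1, 2.0), (1, 5.5)])
        out = aggregate_daily_worst(s, CFG["lactate"])
        assert out.observations == ((1, 5.5),)

    def test_single_observation_per_day_unchanged(self):
        s = series("PT", [(1, 12.0), (3, 13.5)])
        assert aggregate_daily_worst(s, CFG["PT"]).observations == s.observations

    @given(
        st.lists(
            st.tuples(st.integers(1, 10), st.integers(0, 40)), min_size=1, max_size=30
        )
    )
    def test_idempotent(self, raw):
        s = series("platelet", sorted((d, float(v)) for d, v in raw))
        once = aggregate_daily_worst(s, CFG["platelet"])
        twice = aggregate_daily_worst(once, CFG["platelet"])
        assert once.observations == twice.observations


class TestOrient:
    def test_platelet_negated(self):
        s = series("platelet", [(1, 230.0)])
        assert orient(s, CFG["platelet"]).daily == ((1, -230.0),)

    def test_pt_passes_through(self):
        s = series("PT", [(1, 12.0)])
        assert orient(s, CFG["PT"]).daily == ((1, 12.0),)

    def test_double_orientation_refused(self):
        s = orient(series("PT", [(1, 12.0)]), CFG["PT"])
        with pytest.raises(ValueError, match="already oriented"):
            orient(s, CFG["PT"])

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_order_reversing_for_lower_is_worse(self, a, b):
        if a == b:
            return
        lo, hi = sorted([a, b])
        s = series("platelet", [(1, lo), (2, hi)])
        oriented = dict(orient(s, CFG["platelet"]).daily)
        assert oriented[1] > oriented[2]


class TestBaselineValue:
    def test_day1_lookup(self):
        s = OrientedDailySeries("p", "PT", ((1, 5.0), (3, 7.0)))
        assert baseline_value(s) == 5.0

    def test_day2_fallback(self):
        s = OrientedDailySeries("p", "PT", ((2, 4.0),))
        assert baseline_value(s) == 4.0

    def test_outside_window_is_missing(self):
        s = OrientedDailySeries("p", "PT", ((4, 4.0),))
        assert baseline_value(s) is None

    def test_empty_series_is_missing(self):
        assert baseline_value(OrientedDailySeries("p", "PT", ())) is None


class TestMarkerAt:
    def test_carry_forward(self):
        s = OrientedDailySeries("p", "PT", ((1, 3.0), (4, 6.0)))
        assert marker_at(s, 6) == 6.0

    def test_exact_hit(self):
        s = OrientedDailySeries("p", "PT", ((1, 3.0),))
        assert marker_at(s, 1) == 3.0

    def test_nothing_to_carry(self):
        s = OrientedDailySeries("p", "PT", ((2, 3.0),))
        assert marker_at(s, 1) is None

    def test_staleness_bound(self):
        s = OrientedDailySeries("p", "PT", ((1, 3.0),))
        assert marker_at(s, 5, max_staleness=3) is None
        assert marker_at(s, 4, max_staleness=3) == 3.0

    @given(
        st.lists(
            st.tuples(st.integers(1, 30), st.floats(0, 100, allow_nan=False)),
            min_size=1,
            max_size=10,
            unique_by=lambda t: t[0],
        ),
        st.integers(1, 35),
    )
    def test_piecewise_constant_right_continuous(self, obs, day):
        """LOCF equals the value at the latest observed day <= query day."""
        obs = sorted(obs)
        s = OrientedDailySeries("p", "PT", tuple(obs))
        expected = None
        for d, v in obs:
            if d <= day:
                expected = v
        assert marker_at(s, day) == expected


def test_panel_agrees_with_per_series_path():
    """The vectorized panel is exactly the composition of the per-series ops."""
    cohort = generate(SimulationConfig(n_subjects=25, seed=3))
    for marker in ("platelet", "lactate"):
        panel = marker_panel(cohort, marker, max_day=21)
        cfg = cohort.configs[marker]
        for i, sid in enumerate(panel.subject_ids):
            ods = orient(aggregate_daily_worst(cohort.series(sid, marker), cfg), cfg)
            base = baseline_value(ods)
            if base is None:
                assert np.isnan(panel.baseline[i])
            else:
                assert panel.baseline[i] == base
            exit_day = cohort.subject(sid).exit_day
            for day in (1, 2, 7, min(21, exit_day)):
                expected = marker_at(ods, day)
                got = panel.locf[i, day - 1]
                if expected is None:
                    assert np.isnan(got)
                else:
                    assert got == expected
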