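"""Cohort model: readers, writers, validation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tvroc.cohort import Cohort, read_cohort, write_table
from tvroc.errors import (
    ConfigurationError,
    ParseError,
    ReferentialError,
    SchemaError,
)
from tvroc.simulate import SimulationConfig, generate

from conftest import constant_series, subject

SUBJ_HEADER = "id,exit_day,event,age,sex,tbsa,inhalation,burn_type\n"
MEAS_HEADER = "id,marker,day,value\n"


def write_pair(tmp_path, subj_rows, meas_rows):
    sp = tmp_path / "subjects.csv"
    mp = tmp_path / "measurements.csv"
    sp.write_text(SUBJ_HEADER + "".join(subj_rows))
    mp.write_text(MEAS_HEADER + "".join(meas_rows))
    return sp, mp


class TestReadCohort:
    def test_toy_pair_builds_cohort(self, tmp_path):
        sp, mp = write_pair(
            tmp_path,
            ["p1,7,0,50,1,20,0,flame\n", "p2,3,1,60,0,40,1,scald\n"],
            ["p1,lactate,1,2.5\n", "p1,lactate,2,3.0\n", "p2,PT,1,12.1\n"],
        )
        cohort = read_cohort(sp, mp)
        assert cohort.n_subjects == 2
        assert cohort.n_observations == 3
        assert cohort.subject("p2").event == 1

    def test_observation_after_exit_is_referential_error(self, tmp_path):
        sp, mp = write_pair(
            tmp_path, ["p1,7,0,50,1,20,0,flame\n"], ["p1,lactate,9,2.0\n"]
        )
        with pytest.raises(ReferentialError, match="day 9"):
            read_cohort(sp, mp)

    def test_empty_measurement_file(self, tmp_path):
        sp, mp = write_pair(tmp_path, ["p1,7,0,50,1,20,0,flame\n"], [])
        cohort = read_cohort(sp, mp)
        assert cohort.n_subjects == 1
        assert cohort.n_observations == 0

    def test_missing_column_names_the_column(self, tmp_path):
        sp = tmp_path / "s.csv"
        sp.write_text("id,exit_day,event,age,sex,tbsa,inhalation\np1,7,0,50,1,20,0\n")
        mp = tmp_path / "m.csv"
        mp.write_text(MEAS_HEADER)
        with pytest.raises(SchemaError, match="burn_type"):
            read_cohort(sp, mp)

    def test_non_numeric_value_reports_row(self, tmp_path):
        sp, mp = write_pair(
            tmp_path,
            ["p1,7,0,50,1,20,0,flame\n"],
            ["p1,lactate,1,2.0\n", "p1,lactate,2,oops\n"],
        )
        with pytest.raises(ParseError, match="row 2"):
            read_cohort(sp, mp)

    def test_orphan_measurement(self, tmp_path):
        sp, mp = write_pair(
            tmp_path, ["p1,7,0,50,1,20,0,flame\n"], ["ghost,lactate,1,2.0\n"]
        )
        with pytest.raises(ReferentialError, match="ghost"):
            read_cohort(sp, mp)

    def test_unknown_marker_rejected(self, tmp_path):
        sp, mp = write_pair(
            tmp_path, ["p1,7,0,50,1,20,0,flame\n"], ["p1,troponin,1,2.0\n"]
        )
        with pytest.raises(ConfigurationError, match="troponin"):
            read_cohort(sp, mp)


class TestWriteTable:
    def test_three_row_table_is_four_lines(self, tmp_path):
        df = pd.DataFrame({"week": [1, 2, 3], "auc": [0.71234, 0.65, 0.6]})
        path = tmp_path / "t.csv"
        write_table(df, path)
        assert len(path.read_text().strip().splitlines()) == 4

    def test_empty_table_is_header_only(self, tmp_path):
        path = tmp_path / "t.csv"
        write_table(pd.DataFrame(columns=["week", "auc"]), path)
        assert path.read_text().strip() == "week,auc"

    def test_write_read_preserves_shape(self, tmp_path):
        df = pd.DataFrame({"a": [1.234567, 2.0], "b": ["x", "y"]})
        path = tmp_path / "t.csv"
        write_table(df, path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["a", "b"]
        assert len(back) == 2


def test_cohort_roundtrip_preserves_counts_and_values(tmp_path):
    cohort = generate(SimulationConfig(n_subjects=40, seed=5))
    sp, mp = tmp_path / "s.csv", tmp_path / "m.csv"
    cohort.to_csv(sp, mp)
    back = read_cohort(sp, mp)
    assert back.n_subjects == cohort.n_subjects
    assert back.n_observations == cohort.n_observations
    np.testing.assert_allclose(
        np.sort(back.measurements["value"].to_numpy()),
        np.sort(cohort.measurements["value"].to_numpy()),
        rtol=1e-5,
    )


@given(
    kind=st.sampled_from(["late_obs", "orphan", "negative_value", "bad_event"]),
    data=st.data(),
)
def test_validation_rejects_randomized_corruptions(kind, data):
    """Every constructed invariant violation is caught at validation."""
    subjects = [subject("p1", 5, 1), subject("p2", 9, 0)]
    series = [constant_series("p1", "lactate", 2.0, [1, 3, 5])]
    cohort = Cohort.from_records(subjects, series)
    subj = cohort.subjects.copy()
    meas = cohort.measurements.copy()
    if kind == "late_obs":
        row = data.draw(st.integers(0, len(meas) - 1))
        meas.loc[row, "day"] = data.draw(st.integers(6, 50))
    elif kind == "orphan":
        row = data.draw(st.integers(0, len(meas) - 1))
        meas.loc[row, "id"] = "nobody"
    elif kind == "negative_value":
        row = data.draw(st.integers(0, len(meas) - 1))
        meas.loc[row, "value"] = -data.draw(
            st.floats(0.1, 100, allow_nan=False, allow_infinity=False)
        )
    else:
        subj.iloc[0, subj.columns.get_loc("event")] = data.draw(st.integers(2, 9))
    with pytest.raises((ReferentialError, ValueError)):
        Cohort(subj, meas, cohort.configs)
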