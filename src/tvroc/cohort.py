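"""Cohort data model and long-format CSV readers/writers.

The cohort is two tables. The *subject* table has one row per ICU stay:
exit day (integer days since admission, admission day = day 1), an event
indicator (1 = death in the ICU; 0 = discharged alive, treated as
right-censoring at the exit day), and admission covariates. The
*measurement* table is long-format repeated labs: one row per
(subject, marker, day, value).

Time convention, used everywhere downstream: integer days since admission
with admission = day 1; a death on day ``d`` keeps the subject in the risk
set through day ``d`` and makes them an incident case at ``t = d``. Week
``k`` spans days ``7(k-1)+1 .. 7k``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ParseError,
    ReferentialError,
    SchemaError,
)

#: The six routinely measured markers the pipeline analyzes.
MARKERS = ("WBC", "platelet", "creatinine", "lactate", "total_bilirubin", "PT")

BURN_TYPES = ("flame", "electrical", "scald", "contact", "chemical")

HIGHER_IS_WORSE = "higher_is_worse"
LOWER_IS_WORSE = "lower_is_worse"

SUBJECT_COLUMNS = ("id", "exit_day", "event", "age", "sex", "tbsa", "inhalation", "burn_type")
MEASUREMENT_COLUMNS = ("id", "marker", "day", "value")


@dataclass(frozen=True)
class MarkerConfig:
    """Orientation and units of one marker.

    ``direction`` states which direction of the raw value is clinically
    worse; it gives "the poorest daily value" an operational meaning and
    drives the orientation step that makes *larger always mean worse*.
    """

    marker: str
    direction: str
    units: str = ""

    def __post_init__(self) -> None:
        if self.direction not in (HIGHER_IS_WORSE, LOWER_IS_WORSE):
            raise ConfigurationError(
                f"direction for {self.marker!r} must be "
                f"'{HIGHER_IS_WORSE}' or '{LOWER_IS_WORSE}', got {self.direction!r}"
            )

    @property
    def sign(self) -> int:
        """+1 if the raw value is already worst-high, -1 if it must be negated."""
        return 1 if self.direction == HIGHER_IS_WORSE else -1


def default_marker_configs() -> dict[str, MarkerConfig]:
    """Default orientation/units for the six markers.

    Platelet count falls with deterioration (consumption coagulopathy,
    marrow suppression), so it is oriented lower-is-worse; the other five
    rise with deterioration.
    """
    return {
        "WBC": MarkerConfig("WBC", HIGHER_IS_WORSE, "10^3/uL"),
        "platelet": MarkerConfig("platelet", LOWER_IS_WORSE, "10^3/uL"),
        "creatinine": MarkerConfig("creatinine", HIGHER_IS_WORSE, "mg/dL"),
        "lactate": MarkerConfig("lactate", HIGHER_IS_WORSE, "mmol/L"),
        "total_bilirubin": MarkerConfig("total_bilirubin", HIGHER_IS_WORSE, "mg/dL"),
        "PT": MarkerConfig("PT", HIGHER_IS_WORSE, "sec"),
    }


@dataclass(frozen=True)
class SubjectRecord:
    """One subject's exit time, outcome and admission covariates."""

    subject_id: str
    exit_day: int
    event: int
    age: float
    sex: int
    tbsa: float
    inhalation: int
    burn_type: str

    def __post_init__(self) -> None:
        if self.exit_day < 1:
            raise ValueError(f"exit_day must be >= 1, got {self.exit_day}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0 or 1, got {self.event}")
        if not 0.0 <= self.tbsa <= 100.0:
            raise ValueError(f"tbsa must lie in [0, 100], got {self.tbsa}")


@dataclass(frozen=True)
class MarkerSeries:
    """Irregular longitudinal measurements of one marker for one subject.

    Observations are (day, value) pairs sorted by day. Before daily-worst
    aggregation a day may repeat; after preprocessing each day is unique.
    """

    subject_id: str
    marker: str
    observations: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        days = [d for d, _ in self.observations]
        if any(d < 1 for d in days):
            raise ValueError("observation days must be >= 1")
        if days != sorted(days):
            raise ValueError("observations must be sorted by day")
        values = np.asarray([v for _, v in self.observations], dtype=float)
        if values.size and (~np.isfinite(values)).any():
            raise ValueError("marker values must be finite")
        if values.size and (values < 0).any():
            raise ValueError("marker values must be nonnegative")

    @property
    def days(self) -> tuple[int, ...]:
        return tuple(d for d, _ in self.observations)


class Cohort:
    """A validated cohort: subject table, measurement table, marker configs.

    ``subjects`` is indexed by subject id; ``measurements`` is long format
    with columns (id, marker, day, value). Construction validates the
    cross-table invariants (no orphan measurements, no observation after a
    subject's exit day); pass ``validate=False`` only for data already
    known valid (e.g. bootstrap resamples of a validated cohort).
    """

    def __init__(
        self,
        subjects: pd.DataFrame,
        measurements: pd.DataFrame,
        configs: Mapping[str, MarkerConfig] | None = None,
        *,
        validate: bool = True,
    ) -> None:
        self.subjects = subjects
        self.measurements = measurements
        self.configs = dict(configs) if configs is not None else default_marker_configs()
        self._row_positions: dict[str, np.ndarray] | None = None
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        subjects: Iterable[SubjectRecord],
        series: Iterable[MarkerSeries] = (),
        configs: Mapping[str, MarkerConfig] | None = None,
    ) -> "Cohort":
        subj_df = pd.DataFrame(
            [
                {
                    "id": s.subject_id,
                    "exit_day": s.exit_day,
                    "event": s.event,
                    "age": s.age,
                    "sex": s.sex,
                    "tbsa": s.tbsa,
                    "inhalation": s.inhalation,
                    "burn_type": s.burn_type,
                }
                for s in subjects
            ]
        )
        if subj_df.empty:
            subj_df = pd.DataFrame(columns=list(SUBJECT_COLUMNS))
        subj_df = subj_df.set_index("id")
        rows = [
            {"id": ser.subject_id, "marker": ser.marker, "day": d, "value": v}
            for ser in series
            for d, v in ser.observations
        ]
        meas_df = pd.DataFrame(rows, columns=list(MEASUREMENT_COLUMNS))
        return cls(subj_df, meas_df, configs)

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        subj = self.subjects
        meas = self.measurements
        for col in SUBJECT_COLUMNS[1:]:
            if col not in subj.columns:
                raise SchemaError(f"subject table is missing column {col!r}")
        for col in MEASUREMENT_COLUMNS:
            if col not in meas.columns:
                raise SchemaError(f"measurement table is missing column {col!r}")
        if subj.index.has_duplicates:
            dup = subj.index[subj.index.duplicated()][0]
            raise ReferentialError(f"duplicate subject id {dup!r}")
        if len(subj):
            if (subj["exit_day"] < 1).any():
                raise ValueError("exit_day must be >= 1 for every subject")
            if not subj["event"].isin([0, 1]).all():
                raise ValueError("event must be 0 or 1 for every subject")
            if ((subj["tbsa"] < 0) | (subj["tbsa"] > 100)).any():
                raise ValueError("tbsa must lie in [0, 100]")
        if len(meas):
            unknown = set(meas["marker"].unique()) - set(self.configs)
            if unknown:
                raise ConfigurationError(
                    f"measurement rows with unknown marker(s): {sorted(unknown)}"
                )
            vals = meas["value"].to_numpy(dtype=float)
            if (~np.isfinite(vals)).any() or (vals < 0).any():
                raise ValueError("marker values must be finite and nonnegative")
            if (meas["day"] < 1).any():
                raise ValueError("observation days must be >= 1")
            orphan = ~meas["id"].isin(subj.index)
            if orphan.any():
                bad = meas.loc[orphan, "id"].iloc[0]
                raise ReferentialError(f"measurement for unknown subject id {bad!r}")
            exit_days = subj["exit_day"].reindex(meas["id"]).to_numpy()
            late = meas["day"].to_numpy() > exit_days
            if late.any():
                row = meas[late].iloc[0]
                raise ReferentialError(
                    f"subject {row['id']!r} has a {row['marker']} observation on "
                    f"day {row['day']} after its exit day"
                )

    # -- accessors --------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_observations(self) -> int:
        return len(self.measurements)

    @property
    def subject_ids(self) -> pd.Index:
        return self.subjects.index

    def subject(self, subject_id: str) -> SubjectRecord:
        row = self.subjects.loc[subject_id]
        return SubjectRecord(
            subject_id=str(subject_id),
            exit_day=int(row["exit_day"]),
            event=int(row["event"]),
            age=float(row["age"]),
            sex=int(row["sex"]),
            tbsa=float(row["tbsa"]),
            inhalation=int(row["inhalation"]),
            burn_type=str(row["burn_type"]),
        )

    def series(self, subject_id: str, marker: str) -> MarkerSeries:
        m = self.measurements
        sel = m[(m["id"] == subject_id) & (m["marker"] == marker)]
        sel = sel.sort_values("day")
        return MarkerSeries(
            subject_id=str(subject_id),
            marker=marker,
            observations=tuple(
                (int(d), float(v)) for d, v in zip(sel["day"], sel["value"])
            ),
        )

    # -- resampling support -----------------------------------------------

    def _positions_by_subject(self) -> dict[str, np.ndarray]:
        if self._row_positions is None:
            idx = pd.Series(np.arange(len(self.measurements)), dtype=np.int64)
            grouped = idx.groupby(self.measurements["id"].to_numpy()).groups
            self._row_positions = {
                k: np.asarray(v, dtype=np.int64) for k, v in grouped.items()
            }
        return self._row_positions

    def resample(self, rng: np.random.Generator) -> "Cohort":
        """Draw subjects with replacement; each draw carries all its series.

        Drawn subjects receive fresh ids (``b0, b1, ...``) so duplicates
        stay distinct subjects in the resampled cohort. This is the
        subject-level nonparametric bootstrap unit.
        """
        n = self.n_subjects
        draw = rng.integers(0, n, size=n)
        new_subj = self.subjects.iloc[draw].copy()
        new_ids = np.array([f"b{i}" for i in range(n)], dtype=object)
        new_subj.index = pd.Index(new_ids, name="id")
        positions = self._positions_by_subject()
        ids = self.subjects.index.to_numpy()
        per_draw = [positions.get(ids[j], _EMPTY_POSITIONS) for j in draw]
        counts = np.fromiter((len(p) for p in per_draw), dtype=np.int64, count=n)
        if counts.sum():
            rows = np.concatenate(per_draw)
            new_meas = self.measurements.iloc[rows].copy()
            new_meas["id"] = np.repeat(new_ids, counts)
            new_meas = new_meas.reset_index(drop=True)
        else:
            new_meas = self.measurements.iloc[:0].copy()
        return Cohort(new_subj, new_meas, self.configs, validate=False)

    def copy(self) -> "Cohort":
        return Cohort(
            self.subjects.copy(), self.measurements.copy(),
            copy.deepcopy(self.configs), validate=False,
        )

    # -- serialization ----------------------------------------------------

    def to_csv(self, subjects_path: str | Path, measurements_path: str | Path) -> None:
        write_table(self.subjects.reset_index(), subjects_path)
        write_table(self.measurements, measurements_path)


_EMPTY_POSITIONS = np.empty(0, dtype=np.int64)


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{what} table is missing column {col!r}")


def _numeric(df: pd.DataFrame, col: str, what: str, integer: bool = False) -> pd.Series:
    coerced = pd.to_numeric(df[col], errors="coerce")
    bad = coerced.isna() & df[col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric {col!r} in {what} table at data row {row + 1}: "
            f"{df[col].iloc[row]!r}"
        )
    if coerced.isna().any():
        row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
        raise ParseError(f"missing {col!r} in {what} table at data row {row + 1}")
    return coerced.astype(np.int64 if integer else float)


def read_cohort(
    subjects_path: str | Path,
    measurements_path: str | Path,
    configs: Mapping[str, MarkerConfig] | None = None,
) -> Cohort:
    """Read and validate a cohort from the two long-format CSV files.

    Raises :class:`SchemaError` for missing columns, :class:`ParseError`
    (with the offending row) for non-numeric cells, and
    :class:`ReferentialError` for orphan measurements or observations
    recorded after a subject's exit day — never a silent drop.
    """
    subj = pd.read_csv(subjects_path)
    meas = pd.read_csv(measurements_path)
    if meas.empty and len(meas.columns) == 0:
        meas = pd.DataFrame(columns=list(MEASUREMENT_COLUMNS))
    _require_columns(subj, SUBJECT_COLUMNS, "subject")
    _require_columns(meas, MEASUREMENT_COLUMNS, "measurement")
    subj = subj.copy()
    subj["exit_day"] = _numeric(subj, "exit_day", "subject", integer=True)
    subj["event"] = _numeric(subj, "event", "subject", integer=True)
    for col in ("age", "tbsa"):
        subj[col] = _numeric(subj, col, "subject")
    for col in ("sex", "inhalation"):
        subj[col] = _numeric(subj, col, "subject", integer=True)
    subj["id"] = subj["id"].astype(str)
    subj = subj.set_index("id")
    meas = meas.copy()
    if len(meas):
        meas["day"] = _numeric(meas, "day", "measurement", integer=True)
        meas["value"] = _numeric(meas, "value", "measurement")
        meas["id"] = meas["id"].astype(str)
    return Cohort(subj, meas, configs)


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with a header row.

    Floats keep at least six significant digits so a write/read round-trip
    preserves every value to serialized precision.
    """
    table.to_csv(path, index=False, float_format="%.6g")
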