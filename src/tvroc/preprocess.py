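"""Turn raw repeated labs into analysis-ready marker processes.

Three conventions, applied in order:

1. **Daily worst.** When a marker was measured several times in one day,
   only the poorest value of that day is kept — the maximum for markers
   where higher is worse, the minimum for platelet count.
2. **Orientation.** Lower-is-worse markers are negated so that, for every
   marker, a *larger oriented value always encodes worse status*. The
   transform is strictly order-reversing, so rank-based AUCs are exact.
3. **LOCF evaluation.** The "updated" marker value at an arbitrary day is
   the last observed oriented value at or before that day
   (last-observation-carried-forward); no interpolation or smoothing.

The *baseline* ("fixed at admission") value is the day-1 observation, with
a fallback to day 2 when admission labs were timestamped past midnight.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    HIGHER_IS_WORSE,
    MarkerConfig,
    MarkerSeries,
)
from .errors import ConfigurationError

#: Latest admission day an observation may fall on and still count as baseline.
BASELINE_WINDOW_DAYS = 2


@dataclass(frozen=True)
class OrientedDailySeries:
    """One subject-marker series after daily-worst collapse and orientation.

    ``daily`` holds (day, oriented_value) with strictly increasing days;
    larger oriented values mean worse status for every marker.
    """

    subject_id: str
    marker: str
    daily: tuple[tuple[int, float], ...]
    orientation_applied: bool = True

    def __post_init__(self) -> None:
        days = [d for d, _ in self.daily]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("daily entries must have strictly increasing days")


def aggregate_daily_worst(series: MarkerSeries, config: MarkerConfig) -> MarkerSeries:
    """Collapse to one value per day: the clinically poorest one.

    Idempotent: a series already holding one value per day passes through
    unchanged.
    """
    if config.marker != series.marker:
        raise ConfigurationError(
            f"config is for {config.marker!r}, series is {series.marker!r}"
        )
    worst: dict[int, float] = {}
    pick = max if config.direction == HIGHER_IS_WORSE else min
    for day, value in series.observations:
        worst[day] = value if day not in worst else pick(worst[day], value)
    return MarkerSeries(
        subject_id=series.subject_id,
        marker=series.marker,
        observations=tuple(sorted(worst.items())),
    )


def orient(series: MarkerSeries, config: MarkerConfig) -> OrientedDailySeries:
    """Orient a collapsed series so larger always means worse.

    Higher-is-worse markers pass through unchanged; lower-is-worse markers
    are negated. Refuses an already-oriented series (orientation is not
    idempotent: negating twice would silently restore raw order).
    """
    if isinstance(series, OrientedDailySeries):
        raise ValueError("series is already oriented")
    sign = config.sign
    return OrientedDailySeries(
        subject_id=series.subject_id,
        marker=series.marker,
        daily=tuple((day, sign * value) for day, value in series.observations),
    )


def baseline_value(series: OrientedDailySeries) -> float | None:
    """Admission ("baseline") oriented value: day 1, falling back to day 2.

    Returns None (missing-baseline signal) for an empty series or when the
    earliest observation falls after the admission window.
    """
    if not series.daily:
        return None
    first_day, first_value = series.daily[0]
    if first_day <= BASELINE_WINDOW_DAYS:
        return first_value
    return None


def marker_at(
    series: OrientedDailySeries, day: int, max_staleness: int | None = None
) -> float | None:
    """Oriented value at ``day`` by last-observation-carried-forward.

    Piecewise constant between observation days and right-continuous in the
    day index. ``max_staleness`` optionally bounds how many days old the
    carried value may be (``0`` = same-day only); default is unlimited
    lookback. Returns None when nothing has been observed at or before
    ``day`` (or only values staler than allowed).
    """
    if day < 1:
        raise ValueError(f"day must be >= 1, got {day}")
    days = [d for d, _ in series.daily]
    pos = bisect_right(days, day) - 1
    if pos < 0:
        return None
    obs_day, value = series.daily[pos]
    if max_staleness is not None and day - obs_day > max_staleness:
        return None
    return value


# ---------------------------------------------------------------------------
# Vectorized panel used by the estimators. One row per subject, aligned to
# the cohort's subject order; NaN encodes the missing-value signal.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerPanel:
    """Per-subject arrays for one marker, ready for risk-set evaluation.

    ``locf[i, d-1]`` is subject ``i``'s oriented LOCF value at day ``d``
    (NaN before the first observation); ``baseline`` is the oriented
    admission value (NaN when missing). ``n_without_marker`` counts the
    subjects with no measurement of this marker at all — they are excluded
    from this marker's analyses.
    """

    marker: str
    subject_ids: np.ndarray
    exit_day: np.ndarray
    event: np.ndarray
    baseline: np.ndarray
    locf: np.ndarray
    n_without_marker: int

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def take(self, rows: np.ndarray) -> "MarkerPanel":
        """Row-resampled view (used by the pipeline's subject bootstrap)."""
        return MarkerPanel(
            marker=self.marker,
            subject_ids=self.subject_ids[rows],
            exit_day=self.exit_day[rows],
            event=self.event[rows],
            baseline=self.baseline[rows],
            locf=self.locf[rows],
            n_without_marker=self.n_without_marker,
        )

    def values(self, mode: str, day: int | None = None) -> np.ndarray:
        """Oriented values in the requested mode.

        ``baseline`` returns the fixed admission values; ``updated``
        returns the LOCF values at ``day``.
        """
        if mode == "baseline":
            return self.baseline
        if mode == "updated":
            if day is None:
                raise ConfigurationError("mode='updated' requires a day")
            d = min(day, self.locf.shape[1])
            return self.locf[:, d - 1]
        raise ConfigurationError(f"mode must be 'baseline' or 'updated', got {mode!r}")


def marker_panel(
    cohort: Cohort,
    marker: str,
    max_day: int = 56,
    max_staleness: int | None = None,
) -> MarkerPanel:
    """Build the per-subject daily panel for one marker.

    Applies daily-worst aggregation and orientation, then forward-fills
    along days 1..``max_day``. Subjects without any measurement of the
    marker get all-NaN rows and are counted in ``n_without_marker``.
    """
    if marker not in cohort.configs:
        raise ConfigurationError(f"no configuration for marker {marker!r}")
    config = cohort.configs[marker]
    meas = cohort.measurements
    sel = meas[meas["marker"] == marker]
    subj_index = cohort.subjects.index
    n = len(subj_index)
    if sel.empty:
        wide = pd.DataFrame(
            np.nan, index=subj_index, columns=pd.RangeIndex(1, max_day + 1)
        )
        n_missing = n
    else:
        agg = "max" if config.direction == HIGHER_IS_WORSE else "min"
        daily = sel.groupby(["id", "day"])["value"].agg(agg)
        oriented = daily * config.sign
        wide = oriented.unstack("day")
        wide = wide.reindex(columns=pd.RangeIndex(1, max_day + 1), index=subj_index)
        n_missing = int(wide.isna().all(axis=1).sum())
    baseline = wide[1].to_numpy(dtype=float)
    if max_day >= 2:
        day2 = wide[2].to_numpy(dtype=float)
        baseline = np.where(np.isnan(baseline), day2, baseline)
    locf = wide.ffill(axis=1, limit=max_staleness).to_numpy(dtype=float)
    return MarkerPanel(
        marker=marker,
        subject_ids=subj_index.to_numpy(),
        exit_day=cohort.subjects["exit_day"].to_numpy(dtype=np.int64),
        event=cohort.subjects["event"].to_numpy(dtype=np.int64),
        baseline=baseline,
        locf=locf,
        n_without_marker=n_missing,
    )
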