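"""Incident/dynamic (I/D) time-dependent ROC and the weighted concordance index.

At each death day ``t`` the cohort splits into incident cases (subjects who
die exactly at ``t``) and dynamic controls (subjects still under
observation beyond ``t``, whether they later die or are discharged alive).
The AUC at ``t`` is the nonparametric rank statistic — the probability
that a random case carries a worse (larger oriented) marker value than a
random control, ties counting one half.

The overall summary is the concordance index: the weighted average of
AUC(t) over death days up to a truncation time ``tau``, with weights
proportional to ``2 * dF(t) * S(t)`` taken from the Kaplan–Meier curve of
the death time, normalized to sum to one over the included days. This is
the standard incident/dynamic integration weight for concordance over a
truncated horizon: it is (twice) the probability that a random subject
pair is comparable at ``t``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from scipy.stats import rankdata

from .cohort import Cohort
from .errors import ConfigurationError, UndefinedAUCError, UndefinedStatisticError
from .preprocess import MarkerPanel, marker_panel
from .weeks import DEFAULT_TAU_DAYS, week_of_day

MODES = ("baseline", "updated")


@dataclass(frozen=True)
class RiskSet:
    """Cases and controls at one death day."""

    t: int
    case_ids: tuple[str, ...]
    control_ids: tuple[str, ...]


@dataclass(frozen=True)
class SurvivalCurve:
    """Kaplan–Meier product-limit step function over death days.

    ``surv[j]`` is S(t) just after the deaths at ``event_days[j]``;
    ``increment[j]`` is dF(t) = S(t-) - S(t), the probability mass the
    product-limit estimate assigns to a death at that day.
    """

    event_days: np.ndarray
    surv: np.ndarray
    increment: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step evaluation (S(0) = 1)."""
        pos = np.searchsorted(self.event_days, t, side="right") - 1
        return 1.0 if pos < 0 else float(self.surv[pos])


@dataclass
class TimeVaryingAUC:
    """I/D AUC at each event day, weekly summaries and the c-index.

    ``points`` rows are (t, auc_t, n_cases, n_controls). ``weekly`` rows
    are (week, weekly_auc, n_events) for weeks with at least one usable
    risk set. ``n_excluded_missing`` counts (risk set, subject) exclusions
    for missing marker values; ``n_dropped_risk_sets`` counts event days
    dropped because a group emptied.
    """

    marker: str
    mode: str
    points: list[tuple[int, float, int, int]]
    weekly: list[tuple[int, float, int]] = field(default_factory=list)
    cindex: float | None = None
    tau: int = DEFAULT_TAU_DAYS
    n_excluded_missing: int = 0
    n_dropped_risk_sets: int = 0


def build_risk_sets(cohort: Cohort) -> list[RiskSet]:
    """One risk set per distinct death day.

    Deaths sharing a day are pooled as cases against the common controls
    (day-resolution data makes same-day deaths indistinguishable in order).
    Risk sets with no controls (e.g. the last exit is a death) are dropped.
    """
    subj = cohort.subjects
    exit_day = subj["exit_day"].to_numpy()
    event = subj["event"].to_numpy()
    ids = subj.index.to_numpy()
    out: list[RiskSet] = []
    for t in np.unique(exit_day[event == 1]):
        cases = ids[(event == 1) & (exit_day == t)]
        controls = ids[exit_day > t]
        if len(controls) == 0:
            continue
        out.append(RiskSet(int(t), tuple(cases), tuple(controls)))
    return out


def id_auc_at(
    case_values: Sequence[float] | np.ndarray,
    control_values: Sequence[float] | np.ndarray,
) -> float:
    """Rank-based AUC of oriented case vs control values at one time.

    Equals the Mann–Whitney statistic scaled to [0, 1]: the fraction of
    case–control pairs where the case is worse, ties counting 0.5.
    Computed through midranks, which is exact and O(n log n).
    """
    cases = np.asarray(case_values, dtype=float)
    controls = np.asarray(control_values, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise UndefinedAUCError("AUC undefined: empty case or control group")
    ranks = rankdata(np.concatenate([cases, controls]))
    rank_sum = ranks[: cases.size].sum()
    n1, n0 = cases.size, controls.size
    return float((rank_sum - n1 * (n1 + 1) / 2) / (n1 * n0))


def km_from_arrays(exit_day: np.ndarray, event: np.ndarray) -> SurvivalCurve:
    """Kaplan–Meier product-limit curve from exit/event arrays."""
    if exit_day.size == 0:
        raise UndefinedStatisticError("Kaplan-Meier curve of an empty cohort")
    kmf = KaplanMeierFitter()
    kmf.fit(exit_day, event_observed=event)
    event_days = np.unique(exit_day[event == 1])
    if event_days.size == 0:
        return SurvivalCurve(
            event_days=event_days.astype(float),
            surv=np.empty(0),
            increment=np.empty(0),
        )
    surv = kmf.survival_function_at_times(event_days).to_numpy(dtype=float)
    before = np.concatenate([[1.0], surv[:-1]])
    return SurvivalCurve(
        event_days=event_days.astype(float), surv=surv, increment=before - surv
    )


def km_curve(cohort: Cohort) -> SurvivalCurve:
    """Kaplan–Meier product-limit curve of the ICU death time.

    Discharge alive is right-censoring: a censored exit only shrinks the
    subsequent risk sets.
    """
    subj = cohort.subjects
    return km_from_arrays(
        subj["exit_day"].to_numpy(), subj["event"].to_numpy()
    )


def concordance(
    points: Sequence[tuple[int, float, int, int]],
    surv: SurvivalCurve,
    tau: int = DEFAULT_TAU_DAYS,
) -> float:
    """KM-weighted average of AUC(t) over event days up to ``tau``.

    Raw weights ``2 * dF(t) * S(t)`` are renormalized over the included
    days, so the c-index is a convex combination of the AUC points.
    """
    days, aucs, weights = [], [], []
    for t, auc, _, _ in points:
        if t > tau:
            continue
        j = np.searchsorted(surv.event_days, t)
        if j >= surv.event_days.size or surv.event_days[j] != t:
            raise UndefinedStatisticError(
                f"no Kaplan-Meier mass at event day {t}; curve/points mismatch"
            )
        days.append(t)
        aucs.append(auc)
        weights.append(2.0 * surv.increment[j] * surv.surv[j])
    if not days:
        raise UndefinedStatisticError(f"no AUC points at or before tau={tau}")
    w = np.asarray(weights)
    total = w.sum()
    if total <= 0:
        # All included deaths carry zero KM mass (cannot happen for a
        # validated curve unless S already hit 0); fall back to equal weights.
        w = np.ones_like(w)
        total = w.sum()
    # dividing the dot product (not the weights) keeps convex combinations
    # of identical AUCs exact (sum(w)/sum(w) == 1.0 bit-for-bit)
    return float(np.dot(w, np.asarray(aucs)) / total)


def weekly_id_summary(
    points: Sequence[tuple[int, float, int, int]],
    n_weeks: int = 8,
) -> list[tuple[int, float, int]]:
    """Event-count-weighted mean AUC per week; weeks without events omitted."""
    out: list[tuple[int, float, int]] = []
    for week in range(1, n_weeks + 1):
        in_week = [(auc, n_c) for t, auc, n_c, _ in points if week_of_day(t) == week]
        if not in_week:
            continue
        n_events = sum(n for _, n in in_week)
        weekly_auc = sum(auc * n for auc, n in in_week) / n_events
        out.append((week, weekly_auc, n_events))
    return out


def _id_points_from_panel(
    panel: MarkerPanel, mode: str, tau: int
) -> tuple[list[tuple[int, float, int, int]], int, int]:
    """AUC at each death day <= tau from a per-subject panel.

    Returns (points, n_excluded_missing, n_dropped_risk_sets). Subjects
    with a missing (NaN) value at a risk-set time are excluded from that
    risk set only.
    """
    exit_day, event = panel.exit_day, panel.event
    points: list[tuple[int, float, int, int]] = []
    n_excluded = 0
    n_dropped = 0
    for t in np.unique(exit_day[event == 1]):
        if t > tau:
            break
        values = panel.values(mode, day=int(t))
        case_mask = (event == 1) & (exit_day == t)
        control_mask = exit_day > t
        if not control_mask.any():
            n_dropped += 1
            continue
        case_vals = values[case_mask]
        control_vals = values[control_mask]
        n_excluded += int(np.isnan(case_vals).sum() + np.isnan(control_vals).sum())
        case_vals = case_vals[~np.isnan(case_vals)]
        control_vals = control_vals[~np.isnan(control_vals)]
        if case_vals.size == 0 or control_vals.size == 0:
            n_dropped += 1
            continue
        points.append(
            (int(t), id_auc_at(case_vals, control_vals), case_vals.size, control_vals.size)
        )
    return points, n_excluded, n_dropped


def id_curve(
    cohort: Cohort,
    marker: str,
    mode: str,
    tau: int = DEFAULT_TAU_DAYS,
    max_staleness: int | None = None,
) -> TimeVaryingAUC:
    """I/D AUC at every death day up to ``tau`` for one marker and mode.

    ``mode='baseline'`` scores every risk set with the fixed admission
    value; ``mode='updated'`` uses the LOCF value at the risk-set day.
    """
    if mode not in MODES:
        raise ConfigurationError(f"mode must be one of {MODES}, got {mode!r}")
    panel = marker_panel(cohort, marker, max_day=tau, max_staleness=max_staleness)
    points, n_excl, n_drop = _id_points_from_panel(panel, mode, tau)
    return TimeVaryingAUC(
        marker=marker,
        mode=mode,
        points=points,
        tau=tau,
        n_excluded_missing=n_excl,
        n_dropped_risk_sets=n_drop,
    )


def analyze_id(
    cohort: Cohort,
    marker: str,
    mode: str,
    tau: int = DEFAULT_TAU_DAYS,
    max_staleness: int | None = None,
) -> TimeVaryingAUC:
    """Full I/D analysis: AUC points, weekly summaries and the c-index."""
    result = id_curve(cohort, marker, mode, tau=tau, max_staleness=max_staleness)
    result.weekly = weekly_id_summary(result.points)
    if result.points:
        result.cindex = concordance(result.points, km_curve(cohort), tau=tau)
    return result
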