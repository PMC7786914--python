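"""Cumulative/dynamic (C/D) weekly ROC on the at-risk subset.

For week ``k`` the eligible subjects are those still in the ICU at the
week's start (exit day beyond day ``7(k-1)``). Positives are the eligible
subjects who die during week ``k`` (days ``7(k-1)+1 .. 7k``); every other
eligible subject — discharged alive during the week, or still in the unit
past day ``7k`` — is a negative. Across weeks the positive groups are
disjoint and together exhaust all deaths, so the weekly positive counts
partition the death toll.

This is a plain two-group comparison on the weekly subset, exactly as the
weekly risk-set counts imply; no inverse-probability-of-censoring
weighting is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import Cohort
from .errors import ConfigurationError, UndefinedAUCError
from .incident import id_auc_at
from .preprocess import MarkerPanel, marker_panel
from .weeks import N_WEEKS, week_end, week_start

#: Which updated value enters week k: the LOCF value at the week's first
#: day (prediction-style, default) or the last value before exit.
UPDATED_AT_WEEK_START = "week_start"
UPDATED_AT_EXIT = "last_before_exit"


@dataclass(frozen=True)
class CDEstimate:
    """One week's C/D allocation, ROC curve and AUC."""

    week: int
    tau: int
    n_pos: int
    n_neg: int
    auc: float
    #: ROC step curve, or None when the caller asked only for the AUC.
    roc: tuple[tuple[float, float], ...] | None = None


def weekly_subset(cohort: Cohort, week: int) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Allocate positives (deaths within the week) and negatives for week k."""
    if not 1 <= week <= N_WEEKS:
        raise ConfigurationError(f"week must be in 1..{N_WEEKS}, got {week}")
    subj = cohort.subjects
    exit_day = subj["exit_day"].to_numpy()
    event = subj["event"].to_numpy()
    ids = subj.index.to_numpy()
    eligible = exit_day > week_start(week) - 1
    pos = eligible & (event == 1) & (exit_day <= week_end(week))
    neg = eligible & ~pos
    return tuple(ids[pos]), tuple(ids[neg])


def cd_auc(
    pos_values: Sequence[float] | np.ndarray,
    neg_values: Sequence[float] | np.ndarray,
) -> float:
    """Rank-based AUC of the weekly two-group comparison.

    Same pairwise statistic (ties 0.5) as the incident/dynamic AUC, and
    exactly the trapezoidal area under :func:`cd_roc`.
    """
    return id_auc_at(pos_values, neg_values)


def cd_roc(
    pos_values: Sequence[float] | np.ndarray,
    neg_values: Sequence[float] | np.ndarray,
) -> tuple[tuple[float, float], ...]:
    """Full ROC step curve, thresholds swept over the observed values.

    A subject is called positive when its oriented value is worse than or
    equal to the threshold. Curve runs from (0, 0) to (1, 1) with both
    coordinates non-decreasing; tied pos/neg values produce diagonal
    segments whose trapezoidal area matches the 0.5 tie convention.
    """
    pos = np.asarray(pos_values, dtype=float)
    neg = np.asarray(neg_values, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise UndefinedAUCError("ROC undefined: empty positive or negative group")
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    points = [(0.0, 0.0)]
    for thr in thresholds:
        tpr = float((pos >= thr).mean())
        fpr = float((neg >= thr).mean())
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return tuple(points)


def trapezoid_area(roc: Sequence[tuple[float, float]]) -> float:
    fpr = np.asarray([p[0] for p in roc])
    tpr = np.asarray([p[1] for p in roc])
    return float(np.trapezoid(tpr, fpr))


def _cd_values_for_week(
    panel: MarkerPanel, mode: str, week: int, updated_at: str
) -> np.ndarray:
    if mode == "baseline":
        return panel.baseline
    if updated_at == UPDATED_AT_WEEK_START:
        return panel.values("updated", day=week_start(week))
    if updated_at == UPDATED_AT_EXIT:
        # last LOCF value the subject carries before leaving (capped at tau)
        day_idx = np.minimum(panel.exit_day, panel.locf.shape[1]) - 1
        return panel.locf[np.arange(panel.n_subjects), day_idx]
    raise ConfigurationError(f"unknown updated_at rule {updated_at!r}")


def weekly_cd_table(
    cohort: Cohort,
    marker: str,
    mode: str,
    n_weeks: int = N_WEEKS,
    updated_at: str = UPDATED_AT_WEEK_START,
    max_staleness: int | None = None,
    with_roc: bool = False,
) -> list[CDEstimate]:
    """C/D estimate per week for one marker and mode.

    Updated values default to the LOCF value at the week's first day, so
    the comparison stays a prediction of the coming week rather than a
    read-out of values measured while the event unfolded. Subjects with a
    missing value are dropped from that week only. Weeks where either
    group empties are omitted.
    """
    if mode not in ("baseline", "updated"):
        raise ConfigurationError(f"mode must be 'baseline' or 'updated', got {mode!r}")
    panel = marker_panel(
        cohort, marker, max_day=week_end(n_weeks), max_staleness=max_staleness
    )
    exit_day, event = panel.exit_day, panel.event
    out: list[CDEstimate] = []
    for week in range(1, n_weeks + 1):
        eligible = exit_day > week_start(week) - 1
        pos_mask = eligible & (event == 1) & (exit_day <= week_end(week))
        neg_mask = eligible & ~pos_mask
        values = _cd_values_for_week(panel, mode, week, updated_at)
        pos_vals = values[pos_mask]
        neg_vals = values[neg_mask]
        pos_vals = pos_vals[~np.isnan(pos_vals)]
        neg_vals = neg_vals[~np.isnan(neg_vals)]
        if pos_vals.size == 0 or neg_vals.size == 0:
            continue
        roc = cd_roc(pos_vals, neg_vals) if with_roc else None
        out.append(
            CDEstimate(
                week=week,
                tau=week_end(week),
                n_pos=int(pos_vals.size),
                n_neg=int(neg_vals.size),
                auc=cd_auc(pos_vals, neg_vals),
                roc=roc,
            )
        )
    return out


def weekly_counts(cohort: Cohort, n_weeks: int = N_WEEKS) -> list[tuple[int, int, int]]:
    """(week, n_pos, n_neg) allocation counts, before any marker filtering.

    Reproduces the weekly survivor / non-survivor count table: the weekly
    positive column sums to the number of deaths by day ``7 * n_weeks``.
    """
    out = []
    for week in range(1, n_weeks + 1):
        pos, neg = weekly_subset(cohort, week)
        out.append((week, len(pos), len(neg)))
    return out
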