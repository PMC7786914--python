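"""End-to-end orchestration: both ROC approaches, all markers, both modes,
bootstrap confidence intervals, and the result tables.

The bootstrap here resamples *rows of precomputed per-subject panels*.
Every quantity the pipeline reports (baseline value, LOCF row, exit day,
event flag) is a pure per-subject feature, so drawing subject rows with
replacement is exactly the subject-level bootstrap of the resampling
module, at a fraction of the cost — one panel build instead of one per
resample, and every statistic shares the same resamples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bootstrap import DEFAULT_LEVEL, DEFAULT_N_BOOT, summarize_draws
from .cohort import Cohort, MARKERS, write_table
from .cumulative import UPDATED_AT_WEEK_START, weekly_counts
from .errors import ConfigurationError
from .incident import (
    MODES,
    _id_points_from_panel,
    km_from_arrays,
    concordance,
    weekly_id_summary,
)
from .preprocess import MarkerPanel, marker_panel
from .summary import summarize
from .weeks import DEFAULT_TAU_DAYS, N_WEEKS, week_end, week_start


@dataclass(frozen=True)
class AnalysisConfig:
    """Options of one pipeline run."""

    markers: tuple[str, ...] = MARKERS
    modes: tuple[str, ...] = ("baseline", "updated")
    n_weeks: int = N_WEEKS
    tau: int = DEFAULT_TAU_DAYS
    n_boot: int = DEFAULT_N_BOOT
    level: float = DEFAULT_LEVEL
    seed: int = 0
    updated_at: str = UPDATED_AT_WEEK_START
    max_staleness: int | None = None

    def __post_init__(self) -> None:
        if not self.markers:
            raise ConfigurationError("at least one marker must be selected")
        if not self.modes or any(m not in MODES for m in self.modes):
            raise ConfigurationError(f"modes must be a nonempty subset of {MODES}")


def _cd_stats(panel: MarkerPanel, mode: str, week: int, updated_at: str) -> tuple[float, int, int]:
    """(auc, n_pos, n_neg) for one week; NaN AUC when a group empties."""
    from .cumulative import _cd_values_for_week
    from .incident import id_auc_at

    exit_day, event = panel.exit_day, panel.event
    eligible = exit_day > week_start(week) - 1
    pos_mask = eligible & (event == 1) & (exit_day <= week_end(week))
    neg_mask = eligible & ~pos_mask
    values = _cd_values_for_week(panel, mode, week, updated_at)
    pos = values[pos_mask]
    neg = values[neg_mask]
    pos = pos[~np.isnan(pos)]
    neg = neg[~np.isnan(neg)]
    if pos.size == 0 or neg.size == 0:
        return np.nan, int(pos.size), int(neg.size)
    return id_auc_at(pos, neg), int(pos.size), int(neg.size)


def _stat_vector(
    panels: dict[str, MarkerPanel],
    config: AnalysisConfig,
    rows: np.ndarray | None,
) -> tuple[pd.Series, dict]:
    """All reported scalars for one (re)sample, keyed 'approach|mode|marker|which'.

    ``rows`` selects a bootstrap resample; None means the original cohort.
    Also returns the count/meta sidecar (only meaningful for the original).
    """
    values: dict[str, float] = {}
    meta: dict = {}
    first = next(iter(panels.values()))
    if rows is not None:
        first = first.take(rows)
    surv = km_from_arrays(first.exit_day, first.event)
    for marker in config.markers:
        panel = panels[marker]
        if rows is not None:
            panel = panel.take(rows)
        for mode in config.modes:
            points, n_excl, n_drop = _id_points_from_panel(panel, mode, config.tau)
            weekly = weekly_id_summary(points, n_weeks=config.n_weeks)
            weeks_present = {}
            for week, auc, n_events in weekly:
                values[f"id|{mode}|{marker}|w{week}"] = auc
                weeks_present[week] = n_events
            for week in range(1, config.n_weeks + 1):
                values.setdefault(f"id|{mode}|{marker}|w{week}", np.nan)
            try:
                values[f"id|{mode}|{marker}|cindex"] = (
                    concordance(points, surv, tau=config.tau) if points else np.nan
                )
            except Exception:
                values[f"id|{mode}|{marker}|cindex"] = np.nan
            cd_counts = {}
            for week in range(1, config.n_weeks + 1):
                auc, n_pos, n_neg = _cd_stats(panel, mode, week, config.updated_at)
                values[f"cd|{mode}|{marker}|w{week}"] = auc
                cd_counts[week] = (n_pos, n_neg)
            meta[(marker, mode)] = {
                "id_week_events": weeks_present,
                "id_excluded_missing": n_excl,
                "id_dropped_risk_sets": n_drop,
                "cd_counts": cd_counts,
                "n_without_marker": panel.n_without_marker,
            }
    return pd.Series(values), meta


def _assemble_tables(
    ci: pd.DataFrame, meta: dict, config: AnalysisConfig
) -> dict[str, pd.DataFrame]:
    tables: dict[str, pd.DataFrame] = {}
    for mode in config.modes:
        id_rows, cd_rows = [], []
        for marker in config.markers:
            m = meta[(marker, mode)]
            for week in range(1, config.n_weeks + 1):
                key = f"id|{mode}|{marker}|w{week}"
                if key in ci.index and not np.isnan(ci.loc[key, "estimate"]):
                    id_rows.append(
                        {
                            "marker": marker,
                            "week": week,
                            "auc": ci.loc[key, "estimate"],
                            "ci_low": ci.loc[key, "lower"],
                            "ci_high": ci.loc[key, "upper"],
                            "n_cases": m["id_week_events"].get(week, 0),
                        }
                    )
            ckey = f"id|{mode}|{marker}|cindex"
            id_rows.append(
                {
                    "marker": marker,
                    "week": "c-index",
                    "auc": ci.loc[ckey, "estimate"],
                    "ci_low": ci.loc[ckey, "lower"],
                    "ci_high": ci.loc[ckey, "upper"],
                    "n_cases": sum(m["id_week_events"].values()),
                }
            )
            for week in range(1, config.n_weeks + 1):
                key = f"cd|{mode}|{marker}|w{week}"
                n_pos, n_neg = m["cd_counts"][week]
                if np.isnan(ci.loc[key, "estimate"]):
                    continue
                cd_rows.append(
                    {
                        "marker": marker,
                        "week": week,
                        "auc": ci.loc[key, "estimate"],
                        "ci_low": ci.loc[key, "lower"],
                        "ci_high": ci.loc[key, "upper"],
                        "n_pos": n_pos,
                        "n_neg": n_neg,
                    }
                )
        tables[f"id_{mode}"] = pd.DataFrame(id_rows)
        tables[f"cd_{mode}"] = pd.DataFrame(cd_rows)
    return tables


def run_analysis(
    cohort: Cohort,
    config: AnalysisConfig = AnalysisConfig(),
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Run both discrimination approaches with bootstrap CIs.

    Returns (and optionally writes) the result tables: ``id_baseline``,
    ``id_updated``, ``cd_baseline``, ``cd_updated`` (AUC with percentile
    CI per marker-week, plus a c-index row per marker in the ID tables),
    ``counts`` (weekly positives/negatives of the C/D allocation) and
    ``summary`` (the descriptive admission table). A ``run_log`` with the
    seed, exclusion counts and bootstrap failures is written alongside.

    Everything is computed before anything is written, so a failing stage
    leaves no partial output directory.
    """
    for marker in config.markers:
        if marker not in cohort.configs:
            raise ConfigurationError(f"marker {marker!r} has no configuration")
    panels = {
        m: marker_panel(
            cohort, m,
            max_day=max(config.tau, week_end(config.n_weeks)),
            max_staleness=config.max_staleness,
        )
        for m in config.markers
    }
    estimate, meta = _stat_vector(panels, config, rows=None)

    rng = np.random.default_rng(config.seed)
    n = cohort.n_subjects
    draws = np.full((config.n_boot, len(estimate)), np.nan)
    for b in range(config.n_boot):
        rows = rng.integers(0, n, size=n)
        draws[b] = _stat_vector(panels, config, rows)[0].reindex(estimate.index).to_numpy()
    ci = summarize_draws(estimate, draws, config.level, strict=False)

    tables = _assemble_tables(ci, meta, config)
    tables["counts"] = pd.DataFrame(
        weekly_counts(cohort, config.n_weeks),
        columns=["week", "non_survivors", "survivors"],
    )
    tables["summary"] = summarize(cohort)

    run_log = {
        "seed": config.seed,
        "n_boot": config.n_boot,
        "level": config.level,
        "tau": config.tau,
        "n_subjects": int(n),
        "n_deaths": int((cohort.subjects["event"] == 1).sum()),
        "exclusions": {
            f"{marker}|{mode}": {
                "subjects_without_marker": meta[(marker, mode)]["n_without_marker"],
                "missing_value_exclusions": meta[(marker, mode)]["id_excluded_missing"],
                "dropped_risk_sets": meta[(marker, mode)]["id_dropped_risk_sets"],
            }
            for marker in config.markers
            for mode in config.modes
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            write_table(table, out / f"{name}.csv")
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        cfg = dataclasses.asdict(config)
        (out / "config.json").write_text(json.dumps(cfg, indent=2, default=str))
    tables["run_log"] = pd.DataFrame([{"key": k, "value": json.dumps(v)} for k, v in run_log.items()])
    return tables
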