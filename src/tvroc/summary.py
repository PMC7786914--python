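"""Descriptive survivor vs non-survivor comparison (admission table).

Continuous variables are summarized as median [25th;75th percentile]
(linear-interpolation quartiles, the same rule the bootstrap percentiles
use) and compared with the two-sample rank-sum (Mann–Whitney) test.
Categorical variables are summarized as count (percent) and compared with
the chi-square test on the full contingency table, without continuity
correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, MARKERS
from .errors import ConfigurationError, UndefinedStatisticError
from .preprocess import marker_panel

CONTINUOUS_COVARIATES = ("age", "tbsa")
CATEGORICAL_COVARIATES = ("sex", "inhalation", "burn_type")
DEFAULT_VARIABLES = CONTINUOUS_COVARIATES + CATEGORICAL_COVARIATES + MARKERS


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    survivors: str
    non_survivors: str
    overall: str
    p_value: float
    test_used: str
    n_missing: int


def _median_iqr(x: np.ndarray) -> str:
    x = x[~np.isnan(x)]
    med = np.percentile(x, 50)
    lo, hi = np.percentile(x, [25, 75])
    return f"{med:.1f} [{lo:.1f};{hi:.1f}]"


def _count_pct(x: pd.Series, level) -> str:
    n = int((x == level).sum())
    return f"{n} ({100.0 * n / len(x):.1f}%)" if len(x) else f"{n}"


def _continuous_row(name: str, values: np.ndarray, dead: np.ndarray) -> SummaryRow:
    missing = np.isnan(values)
    g1 = values[~missing & ~dead]
    g2 = values[~missing & dead]
    if g1.size == 0 or g2.size == 0:
        raise UndefinedStatisticError(f"an outcome group is empty for {name!r}")
    p = float(stats.mannwhitneyu(g1, g2, alternative="two-sided").pvalue)
    return SummaryRow(
        variable=name,
        survivors=_median_iqr(g1),
        non_survivors=_median_iqr(g2),
        overall=_median_iqr(values[~missing]),
        p_value=p,
        test_used="rank-sum",
        n_missing=int(missing.sum()),
    )


def _categorical_rows(
    name: str, values: pd.Series, dead: np.ndarray, correction: bool
) -> list[SummaryRow]:
    table = pd.crosstab(values, dead)
    if table.shape[1] < 2 or (table.sum(axis=0) == 0).any():
        raise UndefinedStatisticError(f"an outcome group is empty for {name!r}")
    chi2 = stats.chi2_contingency(table.to_numpy(), correction=correction)
    p = float(chi2.pvalue)
    rows = []
    levels = list(table.index)
    for i, level in enumerate(levels):
        rows.append(
            SummaryRow(
                variable=name if len(levels) == 1 else f"{name}={level}",
                survivors=_count_pct(values[~dead], level),
                non_survivors=_count_pct(values[dead], level),
                overall=_count_pct(values, level),
                p_value=p if i == 0 else np.nan,
                test_used="chi-square" if i == 0 else "",
                n_missing=int(values.isna().sum()) if i == 0 else 0,
            )
        )
    return rows


def chi_square_statistic(table: np.ndarray, correction: bool = False) -> float:
    """Pearson chi-square statistic of a contingency table."""
    res = stats.chi2_contingency(np.asarray(table), correction=correction)
    return float(res.statistic)


def summarize(
    cohort: Cohort,
    variables: tuple[str, ...] = DEFAULT_VARIABLES,
    chi_square_correction: bool = False,
) -> pd.DataFrame:
    """Survivor / non-survivor descriptive table.

    Marker names among ``variables`` are summarized on their *raw*
    admission (baseline-window) values, matching how admission labs are
    tabulated clinically. Rows never drop subjects silently: missing
    values are counted in the ``n_missing`` column.
    """
    subj = cohort.subjects
    if len(subj) == 0:
        raise UndefinedStatisticError("cannot summarize an empty cohort")
    dead = subj["event"].to_numpy() == 1
    rows: list[SummaryRow] = []
    for name in variables:
        if name in CONTINUOUS_COVARIATES or name == "exit_day":
            rows.append(
                _continuous_row(name, subj[name].to_numpy(dtype=float), dead)
            )
        elif name in CATEGORICAL_COVARIATES:
            rows.extend(
                _categorical_rows(name, subj[name], dead, chi_square_correction)
            )
        elif name in cohort.configs:
            panel = marker_panel(cohort, name, max_day=2)
            # undo orientation: the table reports raw admission values
            raw = panel.baseline * cohort.configs[name].sign
            rows.append(_continuous_row(name, raw, dead))
        else:
            raise ConfigurationError(f"unknown summary variable {name!r}")
    out = pd.DataFrame([r.__dict__ for r in rows])
    return out
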