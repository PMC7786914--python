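"""Subject-level bootstrap percentile confidence intervals.

The resampling unit is the subject: each draw carries the whole subject —
outcome, covariates, and every marker series — so within-subject
correlation of repeated measurements survives resampling. Intervals are
plain percentile intervals of the resampled statistics; the percentile
definition is linear interpolation between order statistics (numpy's
default), pinned for bit-reproducibility.

Resamples where the statistic is undefined (for example a bootstrap
cohort with no deaths in some week) are dropped and counted, never
imputed; if more than half of the resamples fail the interval is refused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import DegenerateBootstrapError, UndefinedStatisticError

DEFAULT_N_BOOT = 500
DEFAULT_LEVEL = 0.95


@dataclass(frozen=True)
class BootstrapCI:
    """A point estimate with its bootstrap percentile interval."""

    estimate: float
    lower: float
    upper: float
    n_boot: int
    level: float
    seed: int
    n_failed: int


def percentile_interval(samples: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed percentile interval with linear interpolation."""
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(samples, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def bootstrap_ci(
    statistic: Callable[[Cohort], float],
    cohort: Cohort,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> BootstrapCI:
    """Percentile CI of a scalar cohort statistic by subject resampling.

    ``statistic`` may signal an undefined value by raising
    :class:`UndefinedStatisticError` or returning NaN. Deterministic given
    ``seed``.
    """
    if n_boot < 2:
        raise ValueError(f"n_boot must be >= 2, got {n_boot}")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie in (0, 1), got {level}")
    estimate = float(statistic(cohort))
    rng = np.random.default_rng(seed)
    values = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        resampled = cohort.resample(rng)
        try:
            v = float(statistic(resampled))
        except UndefinedStatisticError:
            v = np.nan
        if np.isnan(v):
            n_failed += 1
            values[b] = np.nan
        else:
            values[b] = v
    if n_failed > n_boot // 2:
        raise DegenerateBootstrapError(
            f"statistic {getattr(statistic, '__name__', statistic)!r} undefined "
            f"on {n_failed}/{n_boot} resamples"
        )
    usable = values[~np.isnan(values)]
    lower, upper = percentile_interval(usable, level)
    return BootstrapCI(
        estimate=estimate,
        lower=lower,
        upper=upper,
        n_boot=n_boot,
        level=level,
        seed=seed,
        n_failed=n_failed,
    )


def bootstrap_table(
    statistics: Callable[[Cohort], "pd.Series"],
    cohort: Cohort,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> pd.DataFrame:
    """Joint bootstrap of a vector of named statistics.

    One pass of subject resampling evaluates every component on each
    resampled cohort, so the components share resamples (and runtime).
    Components undefined on a resample are NaN there and counted in that
    component's ``n_failed``. Returns a DataFrame indexed by component
    name with columns estimate / lower / upper / n_failed.
    """
    estimate = statistics(cohort)
    rng = np.random.default_rng(seed)
    draws = np.full((n_boot, len(estimate)), np.nan)
    for b in range(n_boot):
        resampled = cohort.resample(rng)
        draws[b] = statistics(resampled).reindex(estimate.index).to_numpy()
    return summarize_draws(estimate, draws, level)


def summarize_draws(
    estimate: pd.Series, draws: np.ndarray, level: float, strict: bool = True
) -> pd.DataFrame:
    """Componentwise percentile summary of bootstrap draws (NaN = failed).

    A component undefined on more than half the resamples raises when
    ``strict``; otherwise (the pipeline's joint bootstrap, where sparse
    late weeks routinely lose their events under resampling) it gets NaN
    bounds and keeps its ``n_failed`` count.
    """
    n_boot = draws.shape[0]
    rows = []
    for j, name in enumerate(estimate.index):
        col = draws[:, j]
        usable = col[~np.isnan(col)]
        n_failed = n_boot - usable.size
        if n_failed > n_boot // 2:
            if strict:
                raise DegenerateBootstrapError(
                    f"statistic {name!r} undefined on {n_failed}/{n_boot} resamples"
                )
            rows.append((name, float(estimate.iloc[j]), np.nan, np.nan, n_failed))
            continue
        lo, hi = percentile_interval(usable, level)
        rows.append((name, float(estimate.iloc[j]), lo, hi, n_failed))
    return pd.DataFrame(
        rows, columns=["name", "estimate", "lower", "upper", "n_failed"]
    ).set_index("name")
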