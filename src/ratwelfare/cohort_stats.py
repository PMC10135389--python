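"""Statistical routing for two-group longitudinal rodent studies.

Longitudinal measures (weight, consumption, glucose, temperature) are
compared with an ordinary two-way ANOVA (group x week) followed by
Sidak-corrected per-week group contrasts.  Endpoint measures use a
two-sample Student t-test; ordinal or non-normal endpoints (the maximum
welfare scores) use the Mann-Whitney U test, exact at small sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparisonResult",
    "compare_longitudinal",
    "compare_endpoint",
    "summarize",
    "significance_stars",
]

#: Star ladder used in the figures: *, **, ***, **** .
_STAR_LEVELS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class GroupComparisonResult:
    measure: str
    week: int | str  # protocol week, or "endpoint"
    test: str
    statistic: float
    p_value: float
    group_means: dict[str, tuple[float, float]]  # group -> (mean, sd)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def summarize(values: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) standard deviation.

    A singleton has SD 0, matching the "mean +/- 0.00" table style.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = 0.0 if arr.size == 1 else float(arr.std(ddof=1))
    return float(arr.mean()), sd


def significance_stars(p: float) -> str:
    for threshold, stars in _STAR_LEVELS:
        if p < threshold:
            return stars
    return "ns"


def _sidak(p: float, m: int) -> float:
    """Sidak adjustment of a raw p-value for m comparisons."""
    return float(1.0 - (1.0 - min(p, 1.0)) ** m)


def compare_longitudinal(
    data: pd.DataFrame,
    *,
    measure: str = "value",
    value_col: str = "value",
    group_col: str = "group",
    week_col: str = "week",
) -> list[GroupComparisonResult]:
    """Two-way ANOVA (group x week) with Sidak-corrected weekly contrasts.

    ``data`` is tidy: one row per animal-week with the group label, the
    protocol week, and the measured value.  The per-week group contrast
    uses the pooled residual mean square of the full factorial model
    (the convention of standard ANOVA post-tests), with the raw p-value
    Sidak-adjusted for the number of weeks.  Returns one result per week.
    """
    df = data[[group_col, week_col, value_col]].dropna()
    groups = sorted(df[group_col].unique())
    weeks = sorted(df[week_col].unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    if len(weeks) < 2:
        raise ValueError("at least two weeks required")
    counts = df.groupby([group_col, week_col])[value_col].count()
    if (counts < 2).any():
        raise ValueError("every group-week cell needs at least two animals")

    # Full factorial cell-means fit; the residual MS pools within-cell
    # variance across all cells.
    cell_means = df.groupby([group_col, week_col])[value_col].transform("mean")
    resid = df[value_col] - cell_means
    n_cells = len(groups) * len(weeks)
    df_resid = len(df) - n_cells
    mse = float((resid**2).sum() / df_resid)

    results: list[GroupComparisonResult] = []
    m = len(weeks)
    for wk in weeks:
        sub = df[df[week_col] == wk]
        a = sub[sub[group_col] == groups[0]][value_col].to_numpy(float)
        b = sub[sub[group_col] == groups[1]][value_col].to_numpy(float)
        se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
        t = float((a.mean() - b.mean()) / se) if se > 0 else 0.0
        p_raw = 2.0 * stats.t.sf(abs(t), df_resid)
        results.append(
            GroupComparisonResult(
                measure=measure,
                week=wk,
                test="two-way ANOVA + Sidak",
                statistic=t,
                p_value=_sidak(p_raw, m),
                group_means={
                    groups[0]: summarize(a),
                    groups[1]: summarize(b),
                },
            )
        )
    return results


def compare_endpoint(
    control: Sequence[float],
    induced: Sequence[float],
    *,
    measure: str = "endpoint",
    force_nonparametric: bool = False,
    welch: bool = False,
) -> GroupComparisonResult:
    """Two-group endpoint comparison.

    Default: classic (pooled-variance) Student t-test; ``welch=True``
    drops the equal-variance assumption.  ``force_nonparametric`` routes
    to the Mann-Whitney U test, used for measures that are not normally
    distributed (e.g. per-animal maximum welfare scores): exact p when
    the combined sample is small (n <= 20) and tie-free, otherwise the
    normal approximation with tie correction.
    """
    a = np.asarray(control, dtype=float)
    b = np.asarray(induced, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")

    if force_nonparametric:
        has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (a.size + b.size <= 20 and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "Mann-Whitney"
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        test = "Welch t-test" if welch else "t-test"

    # Degenerate data (e.g. every observation tied) gives a 0/0 statistic;
    # there is no evidence against the null, so report p = 1.
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return GroupComparisonResult(
        measure=measure,
        week="endpoint",
        test=test,
        statistic=float(res.statistic) if not np.isnan(res.statistic) else 0.0,
        p_value=min(p, 1.0),
        group_means={"control": summarize(a), "induced": summarize(b)},
    )
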