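"""Aggregation, QC and group statistics over per-cell metrics.

Per-cell values are pooled within condition for inference (the displayed
distributions are per-cell); per-well and per-field means are emitted
alongside so well-level inference remains possible.  Group comparisons
are one-way ANOVA with Tukey HSD for more than two groups and the
equal-variance two-sample t-test for two (Welch behind a flag); outliers
are flagged by the Tukey boxplot rule and reported, never removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ConditionSummary",
    "ComparisonResult",
    "significance_stars",
    "summarize",
    "flag_outliers",
    "compare_groups",
    "expected_cell_count_range",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


def significance_stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class ConditionSummary:
    condition: str
    n_cells: int
    mean: float
    ci_lower: float
    ci_upper: float
    ci_defined: bool
    per_well: pd.DataFrame = field(repr=False, default=None)
    per_field: pd.DataFrame = field(repr=False, default=None)
    outlier_flags: Mapping[tuple, np.ndarray] = field(repr=False, default=None)


@dataclass
class ComparisonResult:
    test: str                       # "anova_tukey" or "t_test"
    groups: list[str]
    statistic: float
    p_value: float
    pairwise: pd.DataFrame          # group1, group2, p_adj, stars
    stars: str


def _mean_ci(values: np.ndarray) -> tuple[float, float, float, bool]:
    n = len(values)
    mean = float(np.mean(values))
    if n < 2:
        return mean, np.nan, np.nan, False
    se = float(np.std(values, ddof=1) / np.sqrt(n))
    return mean, mean - _Z95 * se, mean + _Z95 * se, True


def summarize(
    per_cell: pd.DataFrame,
    metric: str,
    condition_col: str = "condition",
    well_cols: Sequence[str] = ("row", "column"),
    field_col: str = "field",
) -> list[ConditionSummary]:
    """Per-condition mean and normal-approximation 95% CI (mean ± 1.96 SE),
    with per-well and per-field means and per-well outlier flags.

    Groups with n < 2 report an undefined CI (flagged, NaN bounds).
    """
    if metric not in per_cell.columns:
        raise KeyError(f"metric {metric!r} not in columns {list(per_cell.columns)}")
    values = per_cell.dropna(subset=[metric])
    out = []
    for cond, grp in values.groupby(condition_col, sort=True):
        mean, lo, hi, defined = _mean_ci(grp[metric].to_numpy())
        per_well = (
            grp.groupby(list(well_cols))[metric].agg(["count", "mean"]).reset_index()
        )
        per_field = (
            grp.groupby(list(well_cols) + [field_col])[metric]
            .agg(["count", "mean"]).reset_index()
        )
        flags = {}
        for wk, wgrp in grp.groupby(list(well_cols)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                flags[wk] = flag_outliers(wgrp[metric].to_numpy())
        out.append(
            ConditionSummary(
                condition=str(cond), n_cells=len(grp), mean=mean,
                ci_lower=lo, ci_upper=hi, ci_defined=defined,
                per_well=per_well, per_field=per_field, outlier_flags=flags,
            )
        )
    return out


def flag_outliers(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Tukey boxplot rule: flag values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR].

    Quartiles use linear interpolation.  Fewer than 4 values: nothing is
    flagged (with a warning) since quartiles are not meaningful.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 4:
        warnings.warn("n < 4: outlier flagging skipped", stacklevel=2)
        return np.zeros(len(values), dtype=bool)
    q1, q3 = np.percentile(values, [25, 75], method="linear")
    iqr = q3 - q1
    return (values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr)


def compare_groups(
    groups: Mapping[str, Sequence[float]],
    design: str = "auto",
    equal_var: bool = True,
) -> ComparisonResult:
    """One-way ANOVA + Tukey HSD (>2 groups) or two-sample t-test (2 groups).

    ``design`` may be "multi", "two" or "auto" (choose by group count).
    The t-test is the equal-variance Student test by default; pass
    ``equal_var=False`` for Welch.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2 and np.var(v) == 0:
            raise ValueError(f"group {k!r} has n < 2 and zero variance")
    if design == "auto":
        design = "two" if len(names) == 2 else "multi"

    if design == "two":
        if len(names) != 2:
            raise ValueError("design='two' requires exactly 2 groups")
        a, b = arrays[names[0]], arrays[names[1]]
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        pairwise = pd.DataFrame(
            [{"group1": names[0], "group2": names[1], "p_adj": p,
              "stars": significance_stars(p)}]
        )
        return ComparisonResult("t_test", names, float(stat), float(p), pairwise,
                                significance_stars(p))

    stat, p = sps.f_oneway(*arrays.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    flat = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(flat, labels, alpha=0.05)
    from itertools import combinations

    pairs = list(combinations(tukey.groupsunique, 2))
    pairwise = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "p_adj": np.asarray(tukey.pvalues, dtype=float),
        }
    )
    pairwise["stars"] = pairwise["p_adj"].map(significance_stars)
    return ComparisonResult("anova_tukey", names, float(stat), float(p), pairwise,
                            significance_stars(p))


def expected_cell_count_range(
    n_wells: int,
    fields_per_well: tuple[int, int],
    cells_per_field: tuple[int, int],
) -> tuple[int, int]:
    """Total per-condition cell-count range implied by an acquisition frame.

    The product of well count, fields per well and cells per field gives
    the bounds on how many cells a condition contributes.
    """
    return (
        n_wells * fields_per_well[0] * cells_per_field[0],
        n_wells * fields_per_well[1] * cells_per_field[1],
    )
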