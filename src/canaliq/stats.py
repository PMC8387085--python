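"""Group-level statistics on histomorphometric parameters.

The study design aggregates ROI measurements upward: ROIs → field means
→ patient means → two-group comparison.  The default unit of analysis
is the *patient* (mean over that patient's fields), matching a design
where group sizes are counted in biopsies, not fields or ROIs.

Descriptives are mean ± sample SD (n−1).  The between-group test is the
two-sided Student's t-test with pooled variance by default; Welch's
correction is available.  Subgroup tables are descriptive only — no
tests are attached to them, as subgroup sizes in this setting are too
small for meaningful inference.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Parameters compared between groups, in report order.
DEFAULT_PARAMETERS = (
    "area",
    "cmgv",
    "perimeter",
    "feret",
    "pf_ratio",
    "solidity",
    "thickness",
)

_TINY_P = float(np.nextafter(0.0, 1.0))  # degenerate-separation sentinel


@dataclass(frozen=True)
class GroupComparison:
    """Two-group descriptives and t-test result for one parameter.

    Test fields (``t_statistic``, ``p_value``) are None when either
    group has fewer than two units.
    """

    parameter_name: str
    group_a: str
    group_b: str
    group_a_mean: float
    group_a_sd: float
    group_a_n: int
    group_b_mean: float
    group_b_sd: float
    group_b_n: int
    t_statistic: float | None
    p_value: float | None
    aggregation_level: str = "patient"
    test: str = "student"


def aggregate(field_table: pd.DataFrame, level: str = "patient") -> pd.DataFrame:
    """Collapse a per-field summary table to the analysis unit.

    ``field_table`` needs columns ``sample_id``, ``field_index``,
    ``group_label``, ``subgroup``, ``n_rois``, plus one column per
    parameter.  Empty fields (``n_rois == 0``) are excluded with a
    warning before aggregation.

    * ``level="patient"``: one row per sample, parameter values averaged
      over that sample's non-empty fields (patients with no non-empty
      field are dropped with a warning);
    * ``level="field"`` / ``"roi"``: pass-through at that granularity.
    """
    if level not in ("patient", "field", "roi"):
        raise ValueError(f"unknown aggregation level {level!r}")
    df = field_table.copy()
    if "n_rois" in df.columns:
        empty = df["n_rois"] == 0
        if empty.any():
            logger.warning("excluding %d empty field(s) from aggregation", int(empty.sum()))
            df = df[~empty]
    if level in ("field", "roi"):
        return df.reset_index(drop=True)

    if df.empty:
        logger.warning("no non-empty fields: aggregate table is empty")
        return df.reset_index(drop=True)
    value_cols = [
        c
        for c in df.columns
        if c not in ("sample_id", "field_index", "group_label", "subgroup")
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    out = (
        df.groupby("sample_id", sort=False)
        .agg({**{c: "mean" for c in value_cols}, "group_label": "first", "subgroup": "first"})
        .reset_index()
    )
    return out


def compare_groups(
    table: pd.DataFrame,
    parameter: str,
    group_col: str = "group_label",
    test: str = "student",
    aggregation_level: str = "patient",
) -> GroupComparison:
    """Descriptives and a two-sided t-test for one parameter.

    ``test="student"`` pools the variances; ``test="welch"`` does not.
    If either group has n < 2, only descriptives are returned and a
    warning is logged.  If both groups have zero within-group variance
    but different means, the test is degenerate: p is reported as the
    smallest positive float with a warning.
    """
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    groups = list(dict.fromkeys(table[group_col]))
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, found {groups}")
    ga, gb = groups
    a = table.loc[table[group_col] == ga, parameter].dropna().to_numpy(float)
    b = table.loc[table[group_col] == gb, parameter].dropna().to_numpy(float)

    def _sd(x):
        return float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan")

    t_stat: float | None
    p_val: float | None
    if len(a) < 2 or len(b) < 2:
        logger.warning(
            "%s: a group has n < 2 (n=%d vs n=%d); descriptives only",
            parameter, len(a), len(b),
        )
        t_stat = p_val = None
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_ind(a, b, equal_var=(test == "student"))
        t_stat, p_val = float(res.statistic), float(res.pvalue)
        if not np.isfinite(t_stat) or p_val == 0.0:
            logger.warning(
                "%s: degenerate separation (zero within-group variance); p -> 0",
                parameter,
            )
            t_stat = float(np.sign(a.mean() - b.mean())) * float("inf")
            p_val = _TINY_P
    return GroupComparison(
        parameter_name=parameter,
        group_a=str(ga),
        group_b=str(gb),
        group_a_mean=float(a.mean()) if len(a) else float("nan"),
        group_a_sd=_sd(a),
        group_a_n=len(a),
        group_b_mean=float(b.mean()) if len(b) else float("nan"),
        group_b_sd=_sd(b),
        group_b_n=len(b),
        t_statistic=t_stat,
        p_value=p_val,
        aggregation_level=aggregation_level,
        test=test,
    )


def subgroup_table(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS,
    group_col: str = "group_label",
    subgroup_col: str = "subgroup",
) -> pd.DataFrame:
    """Descriptive mean ± SD per group total and per subgroup; no tests.

    One row per (group, subgroup-or-total, parameter).  SD is missing
    (NaN) for cells with a single unit.
    """
    params = [p for p in parameters if p in table.columns]
    rows = []
    for g, gdf in table.groupby(group_col, sort=False):
        cells = [("total", gdf)]
        if subgroup_col in gdf.columns and set(gdf[subgroup_col]) != {"none"}:
            cells += [(str(s), sdf) for s, sdf in gdf.groupby(subgroup_col, sort=False)]
        for cell_name, cdf in cells:
            for p in params:
                x = cdf[p].dropna().to_numpy(float)
                rows.append(
                    {
                        "group": g,
                        "subgroup": cell_name,
                        "parameter": p,
                        "n": len(x),
                        "mean": float(x.mean()) if len(x) else float("nan"),
                        "sd": float(np.std(x, ddof=1)) if len(x) >= 2 else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


def compare_all(
    table: pd.DataFrame,
    parameters: tuple[str, ...] = DEFAULT_PARAMETERS,
    group_col: str = "group_label",
    test: str = "student",
    aggregation_level: str = "patient",
) -> tuple[pd.DataFrame, list[GroupComparison]]:
    """Comparison table over all parameters (wide, report-shaped).

    Returns the wide table (one row per parameter: per-group mean, SD,
    n, t, p) and the underlying :class:`GroupComparison` objects.
    """
    comps = []
    for p in parameters:
        if p not in table.columns:
            continue
        comps.append(
            compare_groups(
                table, p, group_col=group_col, test=test,
                aggregation_level=aggregation_level,
            )
        )
    rows = []
    for c in comps:
        rows.append(
            {
                "parameter": c.parameter_name,
                f"{c.group_a}_mean": c.group_a_mean,
                f"{c.group_a}_sd": c.group_a_sd,
                f"{c.group_a}_n": c.group_a_n,
                f"{c.group_b}_mean": c.group_b_mean,
                f"{c.group_b}_sd": c.group_b_sd,
                f"{c.group_b}_n": c.group_b_n,
                "t": c.t_statistic,
                "p": c.p_value,
            }
        )
    return pd.DataFrame(rows), comps
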