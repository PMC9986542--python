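"""Cohort statistics: group summaries, one-sided Mann-Whitney-U battery,
Kolmogorov-Smirnov subgroup check and the R_flavin-vs-redox-ratio regression.

The inferential design mirrors the study protocol: each tumor entity is
compared against the non-tumorous control group with one-sided alternatives
(lifetime greater, redox ratio lower, R_flavin greater), significance at
p < 0.05 with display stars at p < 0.005 (*) and p < 1e-5 (**).  No
multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GROUPS, METRICS

__all__ = [
    "RegressionResult",
    "group_summary",
    "mwu_one_sided",
    "ks_subgroup_check",
    "metric_regression",
    "hypothesis_battery",
    "significance_stars",
    "battery_to_table",
    "violin_summary",
]

#: One-sided alternative per metric for the tumor-vs-control comparisons.
METRIC_ALTERNATIVES = {"tau_ns": "greater", "redox_ratio": "less", "r_flavin": "greater"}

STAR_THRESHOLDS = ((1e-5, "**"), (0.005, "*"))


def group_summary(values) -> tuple[float, float, float]:
    """(median, q25, q75) with linear interpolation between order statistics."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite values")
    q25, med, q75 = np.percentile(values, [25, 50, 75])
    return float(med), float(q25), float(q75)


def mwu_one_sided(tumor_values, ctl_values, alternative: str) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of tumor vs control values.

    The exact null distribution is used for small untied samples
    (n1 + n2 <= 12); otherwise the normal approximation with tie and
    continuity correction.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    x = np.asarray(tumor_values, dtype=float)
    y = np.asarray(ctl_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size + y.size <= 12 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def ks_subgroup_check(subgroup_values: list) -> np.ndarray:
    """Pairwise two-sample KS p-values after per-subgroup z-scoring.

    Used to rule out shape differences among subgroups once location and
    scale are removed.  Returns a symmetric matrix with ones on the diagonal.
    """
    if len(subgroup_values) < 2:
        raise ValueError("need at least two subgroups")
    normalized = []
    for values in subgroup_values:
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError("each subgroup needs at least two values")
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError("zero-variance subgroup cannot be normalized")
        normalized.append((v - v.mean()) / sd)
    k = len(normalized)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = sps.ks_2samp(normalized[i], normalized[j])
            p[i, j] = p[j, i] = res.pvalue
    return p


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of R_flavin on the redox ratio plus the Pearson correlation."""

    pearson_r: float
    slope: float
    intercept: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.pearson_r) > 1 + 1e-12:
            raise ValueError("|r| must not exceed 1")
        if self.n < 3:
            raise ValueError("regression needs n >= 3")


def metric_regression(r_flavin_values, rr_values) -> RegressionResult:
    """Ordinary least squares of R_flavin on the redox ratio."""
    y = np.asarray(r_flavin_values, dtype=float)
    x = np.asarray(rr_values, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs must have equal length")
    if x.size < 3:
        raise ValueError("regression needs n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the redox ratio")
    fit = sps.linregress(x, y)
    return RegressionResult(
        pearson_r=float(fit.rvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
    )


def significance_stars(p: float | None) -> str:
    if p is None:
        return ""
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return ""


def hypothesis_battery(cohort_df: pd.DataFrame) -> pd.DataFrame:
    """Per group x metric: descriptive summary plus one-sided p vs control.

    Returns one row per (metric, group) with columns metric, group, n,
    median, q25, q75, p_value (NaN for the control rows) and stars.
    """
    groups_present = set(cohort_df["group"])
    if "CTL" not in groups_present:
        raise ValueError("cohort contains no CTL group; battery undefined")
    if not groups_present - {"CTL"}:
        raise ValueError("cohort contains no tumor group")
    rows = []
    for metric in METRICS:
        ctl_values = cohort_df.loc[cohort_df["group"] == "CTL", metric].to_numpy()
        for group in GROUPS:
            if group not in groups_present:
                continue
            values = cohort_df.loc[cohort_df["group"] == group, metric].to_numpy()
            med, q25, q75 = group_summary(values)
            if group == "CTL":
                p = None
            else:
                _, p = mwu_one_sided(values, ctl_values, METRIC_ALTERNATIVES[metric])
            rows.append(
                {
                    "metric": metric,
                    "group": group,
                    "n": int(values.size),
                    "median": med,
                    "q25": q25,
                    "q75": q75,
                    "p_value": np.nan if p is None else p,
                    "stars": significance_stars(p),
                }
            )
    return pd.DataFrame(rows)


def battery_to_table(battery: pd.DataFrame) -> pd.DataFrame:
    """Pivot the battery into the familiar metric-block x group table layout."""
    blocks = []
    for metric in METRICS:
        sub = battery[battery["metric"] == metric].set_index("group")
        block = pd.DataFrame(
            {
                group: [
                    sub.loc[group, "median"],
                    sub.loc[group, "q25"],
                    sub.loc[group, "q75"],
                    sub.loc[group, "p_value"],
                ]
                for group in GROUPS
                if group in sub.index
            },
            index=pd.MultiIndex.from_product(
                [[metric], ["median", "q25", "q75", "p_value"]]
            ),
        )
        blocks.append(block)
    return pd.concat(blocks)


def violin_summary(cohort_df: pd.DataFrame, n_grid: int = 64) -> dict:
    """Plot-ready per-group kernel-density summaries for each metric."""
    out: dict = {}
    for metric in METRICS:
        out[metric] = {}
        for group in GROUPS:
            values = cohort_df.loc[cohort_df["group"] == group, metric].to_numpy()
            if values.size < 3 or np.ptp(values) == 0:
                continue
            kde = sps.gaussian_kde(values)
            grid = np.linspace(values.min(), values.max(), n_grid)
            med, q25, q75 = group_summary(values)
            out[metric][group] = {
                "grid": grid.tolist(),
                "density": kde(grid).tolist(),
                "median": med,
                "q25": q25,
                "q75": q75,
                "n": int(values.size),
            }
    return out
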