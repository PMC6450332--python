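"""Cohort demographics: median (range) summaries and two-group comparisons.

Reproduces the study-sample descriptive table from a participant covariate
file: per-group medians with ranges for the five numeric demographic
variables, male/female counts, and two-sided Mann-Whitney U group
comparisons (exact enumeration for small tie-free samples, otherwise the
tie-corrected normal approximation with continuity correction). A Student
t-test p value is reported alongside as a secondary parametric reference,
since published demographic tables are not always explicit about the
variant used.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .volume_io import participants_frame

__all__ = [
    "median_range",
    "mann_whitney_u",
    "demographics_table",
    "DEMOGRAPHIC_VARIABLES",
]

DEMOGRAPHIC_VARIABLES = (
    ("birth_ga_weeks", "Birth gestational age, wk"),
    ("pma_scan_weeks", "Scan postmenstrual age, wk"),
    ("postnatal_age_days", "Scan postnatal age, d"),
    ("birth_weight_kg", "Birth weight, kg"),
    ("head_circumference_cm", "Head circumference, cm"),
)

#: max per-group size for exact Mann-Whitney enumeration on tie-free data
EXACT_N_MAX = 8


def median_range(values) -> tuple[float, float, float]:
    """(median, min, max); the median of an even-sized sample is the mean
    of the two middle order statistics."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty sample")
    if not np.isfinite(arr).all():
        raise ValueError("non-finite values in sample")
    return float(np.median(arr)), float(arr.min()), float(arr.max())


def mann_whitney_u(x, y) -> tuple[float, float, str]:
    """Two-sided Mann-Whitney U test; returns (U of x, p, method used).

    U is computed from mid-rank sums. The exact null enumeration is used
    when the data are tie-free and min(n) <= 8; otherwise the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical across both samples; p = 1")
        return float(x.size * y.size / 2.0), 1.0, "degenerate"
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and min(x.size, y.size) <= EXACT_N_MAX:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(min(res.pvalue, 1.0)), method


def demographics_table(participants) -> pd.DataFrame:
    """Descriptive statistics of the cohort, one row per demographic variable.

    Columns: per-group median/min/max, male/female counts, Mann-Whitney U
    and two-sided p (with the method used), plus a Student t-test p as a
    parametric reference.
    """
    df = participants if isinstance(participants, pd.DataFrame) else participants_frame(list(participants))
    groups = sorted(df["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    missing = [col for col, _ in DEMOGRAPHIC_VARIABLES if col not in df.columns]
    if missing:
        raise ValueError(f"missing demographic variable(s): {missing}")
    ga, gb = "R+", "R-"
    if set(groups) != {ga, gb}:
        ga, gb = groups
    rows = []
    for col, label in DEMOGRAPHIC_VARIABLES:
        xa = df.loc[df["group"] == ga, col].to_numpy(float)
        xb = df.loc[df["group"] == gb, col].to_numpy(float)
        med_a, min_a, max_a = median_range(xa)
        med_b, min_b, max_b = median_range(xb)
        u, p, method = mann_whitney_u(xa, xb)
        p_t = float(stats.ttest_ind(xa, xb).pvalue)
        rows.append(
            {
                "variable": col,
                "label": label,
                f"median_{ga}": med_a,
                f"min_{ga}": min_a,
                f"max_{ga}": max_a,
                f"median_{gb}": med_b,
                f"min_{gb}": min_b,
                f"max_{gb}": max_b,
                "U": u,
                "p_mannwhitney": p,
                "mw_method": method,
                "p_ttest": p_t,
            }
        )
    table = pd.DataFrame(rows)
    counts = df.groupby(["group", "sex"]).size()
    table.attrs["sex_counts"] = {
        g: (int(counts.get((g, "male"), 0)), int(counts.get((g, "female"), 0))) for g in (ga, gb)
    }
    table.attrs["group_sizes"] = {g: int((df["group"] == g).sum()) for g in (ga, gb)}
    return table
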