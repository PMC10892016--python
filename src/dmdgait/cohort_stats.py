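"""Cohort-level statistics: group comparisons, component-feature
correlations, NSAA severity bins, and the community-mobility projection.

Group means of each gait feature are compared per activity with plain
two-tailed Student t-tests (flagged at p < 0.05, no multiplicity
adjustment — descriptive only).  Correlations of projection scores
(PC1/PC2/LDA) with features use Pearson's r, Bonferroni-adjusted within
each (component, activity) row; the ordinal NSAA score uses Spearman's
rank correlation instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .gait_features import FEATURE_NAMES

ALPHA = 0.05


# ---------------------------------------------------------------------------
# group comparisons


def group_ttest(values_a, values_b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sided two-sample t-test (Student by default, Welch via flag).

    Two identical constant groups return (0.0, 1.0) by convention.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def feature_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per (activity, group) mean/SD of each CF plus the DMD-vs-TD p-value.

    Shaped like the standard cohort summary: one block per activity plus
    a pooled "All" block; p-values are bold-flagged at 0.05 without
    adjustment (column ``significant``).
    """
    rows = []
    activities = sorted(table["activity"].unique()) + ["All"]
    for act in activities:
        sub = table if act == "All" else table[table["activity"] == act]
        for feat in FEATURE_NAMES:
            dmd = sub.loc[sub["group"] == "DMD", feat].dropna()
            td = sub.loc[sub["group"] == "TD", feat].dropna()
            if len(dmd) >= 2 and len(td) >= 2:
                _, p = group_ttest(td, dmd)
            else:
                p = float("nan")
            rows.append(
                {
                    "activity": act,
                    "feature": feat,
                    "td_mean": td.mean(),
                    "td_sd": td.std(ddof=1),
                    "dmd_mean": dmd.mean(),
                    "dmd_sd": dmd.std(ddof=1),
                    "p_value": p,
                    "significant": bool(p < ALPHA) if np.isfinite(p) else False,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# component-feature correlations


class CorrMethod(str, Enum):
    PEARSON = "pearson"
    SPEARMAN = "spearman"


@dataclass
class CorrelationCell:
    """One entry of the component-vs-feature correlation table."""

    component: str  # PC1 / PC2 / LDA
    feature: str  # CF name or NSAA
    r: float
    p_adj: float
    method: CorrMethod

    def __post_init__(self) -> None:
        if np.isfinite(self.r):
            assert -1 - 1e-12 <= self.r <= 1 + 1e-12
        assert 0 <= self.p_adj <= 1 or np.isnan(self.p_adj)


def component_correlations(
    scores: pd.DataFrame,
    table: pd.DataFrame,
    component: str,
    activity: str | None = None,
) -> list[CorrelationCell]:
    """Correlate one projection score with the 8 CFs and NSAA.

    ``scores`` must hold ``participant_id`` and the component column;
    rows are matched to ``table`` on participant (and activity when
    given).  Pearson for the continuous CFs, Spearman for the ordinal
    NSAA; p-values are multiplied by the family size (the 9 tests of
    this row) and capped at 1.  Constant series yield an undefined
    (NaN) cell rather than a spurious value.
    """
    sub = table if activity is None else table[table["activity"] == activity]
    merged = sub.merge(scores[["participant_id", component]], on="participant_id")
    if len(merged) < 4:
        raise ValueError("need at least 4 paired observations")
    targets = FEATURE_NAMES + ["nsaa"]
    m = len(targets)
    cells = []
    z = merged[component].to_numpy(dtype=float)
    for feat in targets:
        v = merged[feat].to_numpy(dtype=float)
        ok = np.isfinite(v) & np.isfinite(z)
        method = CorrMethod.SPEARMAN if feat == "nsaa" else CorrMethod.PEARSON
        if ok.sum() < 4 or np.std(v[ok]) == 0 or np.std(z[ok]) == 0:
            r, p_adj = float("nan"), float("nan")
        else:
            if method is CorrMethod.SPEARMAN:
                r, p = stats.spearmanr(z[ok], v[ok])
            else:
                r, p = stats.pearsonr(z[ok], v[ok])
            r = float(r)
            p_adj = min(1.0, float(p) * m)
        cells.append(
            CorrelationCell(
                component=component,
                feature="NSAA" if feat == "nsaa" else feat.upper(),
                r=r,
                p_adj=p_adj,
                method=method,
            )
        )
    return cells


def correlation_table(cells: list[CorrelationCell]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "component": c.component,
                "feature": c.feature,
                "r": c.r,
                "p_adj": c.p_adj,
                "method": c.method.value,
            }
            for c in cells
        ]
    )


# ---------------------------------------------------------------------------
# NSAA severity bands


class NSAASeverity(str, Enum):
    """Functional-severity band from the 0-34 NSAA total score."""

    NEAR_TD = "near_TD"  # >= 30
    MILD = "mild"  # 20-29
    MODERATE = "moderate"  # 10-19
    SEVERE = "severe"  # < 10


def nsaa_band(nsaa: int) -> NSAASeverity:
    """Severity band: near-TD >= 30, mild 20-29, moderate 10-19, severe < 10."""
    if not 0 <= nsaa <= 34:
        raise ValueError(f"NSAA score {nsaa} outside [0, 34]")
    if nsaa >= 30:
        return NSAASeverity.NEAR_TD
    if nsaa >= 20:
        return NSAASeverity.MILD
    if nsaa >= 10:
        return NSAASeverity.MODERATE
    return NSAASeverity.SEVERE


# ---------------------------------------------------------------------------
# community-mobility projection


@dataclass
class MobilityProjection:
    """Daily travel implied by a step count, height, and relative step length."""

    height_cm: float
    daily_steps: float
    sl_fraction: float
    step_length_cm: float
    daily_distance_m: float


def mobility_projection(
    height_cm: float, daily_steps: float, sl_fraction: float
) -> MobilityProjection:
    """Project daily distance from height, steps/day, and step length.

    step_length_cm = sl_fraction x height_cm;
    daily_distance_m = daily_steps x step_length_cm / 100.
    """
    if not (height_cm > 0 and daily_steps > 0 and 0 < sl_fraction < 1):
        raise ValueError("inputs must be positive with sl_fraction in (0, 1)")
    step_cm = sl_fraction * height_cm
    dist_m = daily_steps * step_cm / 100.0
    return MobilityProjection(
        height_cm=height_cm,
        daily_steps=daily_steps,
        sl_fraction=sl_fraction,
        step_length_cm=step_cm,
        daily_distance_m=dist_m,
    )


def mobility_reduction(
    reference: MobilityProjection, other: MobilityProjection
) -> tuple[float, float]:
    """(absolute meters, percent of reference) lost vs the reference scenario.

    The percentage is truncated (not rounded) to 1 decimal, matching the
    conventional presentation of these projections.
    """
    abs_m = reference.daily_distance_m - other.daily_distance_m
    pct = math.floor(1000.0 * abs_m / reference.daily_distance_m + 1e-9) / 10.0
    return abs_m, pct


# ---------------------------------------------------------------------------
# step length by speed / severity


def step_length_by_speed_report(
    table: pd.DataFrame, grouping: str = "NSAA_bands"
) -> pd.DataFrame:
    """Mean step length per (activity, group band) with adjacent-band t-tests.

    grouping == "TD_vs_nearTD_DMD": TD participants vs DMD participants
    with NSAA >= 30 (lower-scoring DMD excluded).
    grouping == "NSAA_bands": DMD participants split by severity band.
    Bands with fewer than 2 members are reported but excluded from
    comparisons (with a warning column).
    """
    if grouping == "TD_vs_nearTD_DMD":
        sub = table[
            (table["group"] == "TD")
            | ((table["group"] == "DMD") & (table["nsaa"] >= 30))
        ].copy()
        sub["band"] = sub["group"]
        order = ["TD", "DMD"]
    elif grouping == "NSAA_bands":
        sub = table[table["group"] == "DMD"].copy()
        sub["band"] = sub["nsaa"].map(lambda s: nsaa_band(int(s)).value)
        order = [b.value for b in NSAASeverity]
    else:
        raise ValueError(f"unknown grouping {grouping!r}")

    rows = []
    for act in sorted(sub["activity"].unique()):
        block = sub[sub["activity"] == act]
        present = [b for b in order if (block["band"] == b).any()]
        stats_by_band = {}
        for band in present:
            vals = block.loc[block["band"] == band, "sl"].dropna()
            stats_by_band[band] = vals
        for i, band in enumerate(present):
            vals = stats_by_band[band]
            p_next = float("nan")
            if i + 1 < len(present):
                nxt = stats_by_band[present[i + 1]]
                if len(vals) >= 2 and len(nxt) >= 2:
                    _, p_next = group_ttest(vals, nxt)
            rows.append(
                {
                    "activity": act,
                    "band": band,
                    "n": len(vals),
                    "sl_mean": vals.mean() if len(vals) else float("nan"),
                    "sl_sd": vals.std(ddof=1) if len(vals) > 1 else float("nan"),
                    "p_vs_next_band": p_next,
                    "comparable": len(vals) >= 2,
                }
            )
    return pd.DataFrame(rows)
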