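"""Sensitivity of population and individual estimates to valid-day rules.

Stricter valid-day rules discard low-wear days, which shifts both the set
of retained subjects and their average daily step count / heart rate. The
functions here quantify that shift: per-(group, rule) population tables,
per-subject signed differences between two rules, binning of absolute
step-count differences into bands aligned with physical-activity level
widths, and a report of subjects whose Tudor-Locke activity category
changes between rules (a misclassification a naive pipeline would commit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import DEFAULT_RULES, ValidDayRule, cohort_summaries, subject_estimates
from .io import Cohort

#: Default absolute step-difference bin edges (the last bin is unbounded).
DEFAULT_DIFF_EDGES: tuple[float, ...] = (0, 500, 1000, 3000, 5000)

#: Tudor-Locke daily-step activity categories, half-open on the left edge.
ACTIVITY_LEVELS: tuple[tuple[float, str], ...] = (
    (0, "sedentary"),
    (5000, "low active"),
    (7500, "somewhat active"),
    (10000, "highly active"),
)


def classify_activity_level(avg_daily_steps: float) -> str:
    """Tudor-Locke category for an average daily step count.

    Bins are half-open: [0, 5000) sedentary, [5000, 7500) low active,
    [7500, 10000) somewhat active, [10000, inf) highly active.
    """
    if avg_daily_steps < 0 or not np.isfinite(avg_daily_steps):
        raise ValueError(f"average daily steps must be finite and >= 0, got {avg_daily_steps}")
    label = ACTIVITY_LEVELS[0][1]
    for edge, name in ACTIVITY_LEVELS:
        if avg_daily_steps >= edge:
            label = name
    return label


def activity_levels(avg_daily_steps: Sequence[float]) -> pd.Series:
    """Vectorized :func:`classify_activity_level`; NaN maps to NaN."""
    x = pd.Series(avg_daily_steps, dtype=float)
    if (x.dropna() < 0).any():
        raise ValueError("average daily steps must be >= 0")
    edges = [e for e, _ in ACTIVITY_LEVELS] + [np.inf]
    labels = [name for _, name in ACTIVITY_LEVELS]
    return pd.cut(x, bins=edges, labels=labels, right=False).astype(object)


def population_estimates(
    cohort: Cohort,
    rules: Sequence[ValidDayRule] = DEFAULT_RULES,
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Group-level estimate table across valid-day rules.

    For each (group, rule): the unweighted mean over subjects (each subject
    counts once) of avg daily steps and avg daily HR, computed over the
    subjects retaining at least one valid day under that rule; the number
    retained; and the mean number of valid days.
    """
    if summaries is None:
        summaries = cohort_summaries(cohort, rules=tuple(rules))
    rows = []
    for rule in rules:
        est = subject_estimates(cohort, rule, summaries=summaries)
        for grp, sub in est.groupby("group", sort=True):
            retained = sub["n_valid_days"] > 0
            rows.append(
                {
                    "group": grp,
                    "rule": rule.name,
                    "n_subjects": len(sub),
                    "n_retained": int(retained.sum()),
                    "mean_n_valid_days": float(sub["n_valid_days"].mean()),
                    "mean_avg_daily_steps": float(sub["avg_daily_steps"].mean())
                    if retained.any()
                    else np.nan,
                    "mean_avg_daily_hr": float(sub["avg_daily_hr"].mean())
                    if sub["avg_daily_hr"].notna().any()
                    else np.nan,
                }
            )
    return pd.DataFrame(rows)


def individual_differences(
    cohort: Cohort,
    rule_a: ValidDayRule,
    rule_b: ValidDayRule,
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject change in estimates between two valid-day rules.

    The signed delta convention is ``estimate(rule_b) - estimate(rule_a)``.
    Subjects lacking an estimate under either rule keep their row with NaN
    deltas and ``both_defined=False`` — they are reported, never silently
    dropped.
    """
    if summaries is None:
        summaries = cohort_summaries(cohort, rules=(rule_a, rule_b))
    a = subject_estimates(cohort, rule_a, summaries=summaries).set_index("subject_id")
    b = subject_estimates(cohort, rule_b, summaries=summaries).set_index("subject_id")
    out = pd.DataFrame(
        {
            "group": a["group"],
            "steps_a": a["avg_daily_steps"],
            "steps_b": b["avg_daily_steps"],
            "hr_a": a["avg_daily_hr"],
            "hr_b": b["avg_daily_hr"],
        }
    )
    out["delta_steps"] = out["steps_b"] - out["steps_a"]
    out["abs_delta_steps"] = out["delta_steps"].abs()
    out["delta_hr"] = out["hr_b"] - out["hr_a"]
    out["abs_delta_hr"] = out["delta_hr"].abs()
    out["both_defined"] = out["steps_a"].notna() & out["steps_b"].notna()
    return out.reset_index()


@dataclass(frozen=True)
class DifferenceBinning:
    """Per-group histogram of absolute step-count differences.

    ``table`` has one row per (group, bin) with count and the fraction of
    that group's subjects possessing estimates under both rules.
    """

    edges: tuple[float, ...]
    table: pd.DataFrame
    n_undefined: int


def bin_differences(
    diffs: pd.DataFrame,
    edges: Sequence[float] = DEFAULT_DIFF_EDGES,
) -> DifferenceBinning:
    """Bin absolute step-count deltas into half-open bands per group.

    With the default edges the bands are [0,500), [500,1000), [1000,3000),
    [3000,5000), [5000,inf). ``diffs`` is the output of
    :func:`individual_differences`; subjects without both estimates are
    excluded from the histogram and counted in ``n_undefined``.
    """
    edges = tuple(float(e) for e in edges)
    if list(edges) != sorted(set(edges)):
        raise ValueError("edges must be strictly increasing")
    defined = diffs.loc[diffs["both_defined"]].copy()
    if not np.isfinite(defined["abs_delta_steps"]).all():
        raise ValueError("deltas must be finite")
    bounds = list(edges) + [np.inf]
    labels = [
        f"[{int(lo)}, {'inf' if np.isinf(hi) else int(hi)})"
        for lo, hi in zip(bounds[:-1], bounds[1:])
    ]
    defined["bin"] = pd.cut(
        defined["abs_delta_steps"], bins=bounds, labels=labels, right=False
    )
    rows = []
    for grp, sub in defined.groupby("group", sort=True):
        counts = sub["bin"].value_counts().reindex(labels).fillna(0).astype(int)
        n = len(sub)
        for label in labels:
            rows.append(
                {
                    "group": grp,
                    "bin": label,
                    "count": int(counts[label]),
                    "fraction": counts[label] / n if n else np.nan,
                }
            )
    table = pd.DataFrame(rows)
    return DifferenceBinning(
        edges=edges,
        table=table,
        n_undefined=int((~diffs["both_defined"]).sum()),
    )


def misclassification_report(
    cohort: Cohort,
    rule_a: ValidDayRule,
    rule_b: ValidDayRule,
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Subjects whose activity category differs between two rules.

    Returns one row per flagged subject with both estimates and both
    categories; subjects lacking an estimate under either rule cannot be
    classified and are omitted.
    """
    diffs = individual_differences(cohort, rule_a, rule_b, summaries=summaries)
    defined = diffs.loc[diffs["both_defined"]].copy()
    defined["category_a"] = activity_levels(defined["steps_a"]).to_numpy()
    defined["category_b"] = activity_levels(defined["steps_b"]).to_numpy()
    flagged = defined.loc[defined["category_a"] != defined["category_b"]]
    return flagged[
        ["subject_id", "group", "steps_a", "steps_b", "category_a", "category_b"]
    ].reset_index(drop=True)
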