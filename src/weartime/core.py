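"""Wear time, daily summaries, and estimates under pluggable valid-day rules.

Wear time for a window is the number of minutes with a registered heart
rate divided by the total minutes in the window — on a consumer wearable
the optical HR sensor only registers a per-minute value while the device
is on-wrist, so HR presence is the wear indicator. Over a full calendar
day the denominator is always 1440.

A "valid day" is a day retained for analysis under a named rule. The three
rules used throughout are:

``none``
    every study day is valid (wear time ignored);
``stepcount1000``
    valid iff the registered daily step count is strictly greater than 1000;
``weartime80``
    valid iff daily wear time is strictly greater than 80% (19.2 hours).

Per-subject estimates (average daily step count, average daily heart rate)
are means over a rule's valid days; with zero valid days the estimate is
undefined rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .io import Cohort, SubjectSeries

MINUTES_PER_DAY = 1440

#: Day-summary validity column prefix, e.g. ``valid_weartime80``.
VALID_PREFIX = "valid_"


@dataclass(frozen=True)
class ValidDayRule:
    """Named predicate deciding whether a day is retained for analysis.

    Parameters
    ----------
    name
        Identifier used in columns (``valid_<name>``) and on the CLI.
    min_steps
        Day is valid only if ``total_steps > min_steps`` (strict). ``None``
        disables the step floor.
    min_wear_fraction
        Day is valid only if ``wear_fraction > min_wear_fraction`` (strict).
        ``None`` disables the wear floor.
    require_any_record
        If set, days with no records at all are invalid even when both
        thresholds are absent. By default a received-but-never-worn device
        contributes 0-step days under the ``none`` rule.
    """

    name: str
    min_steps: int | None = None
    min_wear_fraction: float | None = None
    require_any_record: bool = False

    def __post_init__(self) -> None:
        if self.min_steps is not None and self.min_steps < 0:
            raise ValueError("min_steps must be non-negative")
        if self.min_wear_fraction is not None and not 0.0 <= self.min_wear_fraction <= 1.0:
            raise ValueError("min_wear_fraction must be in [0, 1]")

    @property
    def min_wear_hours(self) -> float | None:
        """The wear floor expressed in hours of a 24-hour day."""
        if self.min_wear_fraction is None:
            return None
        return self.min_wear_fraction * 24.0

    def is_valid(
        self, total_steps: float, wear_fraction: float, n_records: int | None = None
    ) -> bool:
        if self.require_any_record and n_records is not None and n_records == 0:
            return False
        if self.min_steps is not None and not total_steps > self.min_steps:
            return False
        if self.min_wear_fraction is not None and not wear_fraction > self.min_wear_fraction:
            return False
        return True


PRESET_RULES: dict[str, ValidDayRule] = {
    "none": ValidDayRule("none"),
    "stepcount1000": ValidDayRule("stepcount1000", min_steps=1000),
    "weartime80": ValidDayRule("weartime80", min_wear_fraction=0.80),
}

DEFAULT_RULES: tuple[ValidDayRule, ...] = tuple(PRESET_RULES.values())


def get_rule(name: str) -> ValidDayRule:
    """Look up a preset rule by name (case-insensitive)."""
    try:
        return PRESET_RULES[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown rule {name!r}; presets are {sorted(PRESET_RULES)}"
        ) from None


@dataclass(frozen=True)
class DaySummary:
    """Per-subject-per-day aggregates plus validity under registered rules."""

    subject_id: str
    date: date
    wear_minutes: int
    total_steps: int
    mean_hr: float | None
    n_records: int
    validity: dict[str, bool] = field(default_factory=dict)

    @property
    def wear_fraction(self) -> float:
        return self.wear_minutes / MINUTES_PER_DAY


@dataclass(frozen=True)
class SubjectEstimate:
    """A subject's average daily step count / HR under one valid-day rule."""

    subject_id: str
    rule_name: str
    n_valid_days: int
    avg_daily_steps: float | None
    avg_daily_hr: float | None


def window_total_minutes(start: pd.Timestamp, end: pd.Timestamp) -> int:
    """Total minutes in the half-open window ``[start, end)``.

    A full calendar day yields 1440.
    """
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    n = int((end - start) / pd.Timedelta(minutes=1))
    if n < 1:
        raise ValueError("window must span at least one minute")
    return n


def compute_wear_fraction(
    data: pd.DataFrame, start: pd.Timestamp, end: pd.Timestamp
) -> float:
    """Fraction of minutes in ``[start, end)`` with a registered heart rate.

    ``data`` is a minute-indexed frame with a ``heart_rate`` column
    (as in :attr:`~weartime.io.SubjectSeries.data`).
    """
    total = window_total_minutes(start, end)
    idx = data.index
    in_window = (idx >= pd.Timestamp(start)) & (idx < pd.Timestamp(end))
    worn = int(data.loc[in_window, "heart_rate"].notna().sum())
    return worn / total


def summarize_day(
    data: pd.DataFrame,
    subject_id: str,
    day: date,
    rules: tuple[ValidDayRule, ...] = DEFAULT_RULES,
    count_steps_without_hr: bool = True,
) -> DaySummary:
    """Summarize one subject's records for one calendar date.

    ``data`` may contain only records of that date (an empty frame is a
    legal zero-record day). Steps registered in minutes without heart rate
    count toward ``total_steps`` by default but never toward wear minutes.
    """
    if len(data) > 0:
        dates = data.index.normalize().unique()
        if len(dates) > 1 or dates[0].date() != day:
            raise ValueError(f"records span dates {list(dates)}, expected {day}")
    worn = data["heart_rate"].notna() if len(data) else pd.Series(dtype=bool)
    wear_minutes = int(worn.sum())
    if count_steps_without_hr or len(data) == 0:
        steps = data["steps"] if len(data) else pd.Series(dtype=float)
    else:
        steps = data.loc[worn, "steps"]
    total_steps = int(steps.sum()) if len(steps) else 0
    mean_hr = float(data.loc[worn, "heart_rate"].mean()) if wear_minutes else None
    wear_fraction = wear_minutes / MINUTES_PER_DAY
    validity = {
        r.name: r.is_valid(total_steps, wear_fraction, len(data)) for r in rules
    }
    return DaySummary(
        subject_id=subject_id,
        date=day,
        wear_minutes=wear_minutes,
        total_steps=total_steps,
        mean_hr=mean_hr,
        n_records=len(data),
        validity=validity,
    )


def daily_summaries(
    series: SubjectSeries,
    rules: tuple[ValidDayRule, ...] = DEFAULT_RULES,
    count_steps_without_hr: bool = True,
) -> pd.DataFrame:
    """One summary row per calendar day of the subject's study window.

    Days with no records appear with ``wear_minutes=0``, ``total_steps=0``
    and absent ``mean_hr``. Returns a frame with columns ``subject_id``,
    ``date``, ``wear_minutes``, ``wear_fraction``, ``total_steps``,
    ``mean_hr``, ``n_records`` and one ``valid_<rule>`` column per rule.
    """
    dates = series.study_dates()
    df = series.data
    if len(df):
        day = df.index.normalize()
        worn = df["heart_rate"].notna()
        wear = worn.groupby(day).sum()
        if count_steps_without_hr:
            steps = df["steps"].groupby(day).sum()
        else:
            steps = df["steps"].where(worn).groupby(day).sum()
        hr_mean = df["heart_rate"].groupby(day).mean()
        n_rec = df["heart_rate"].groupby(day).size()
    else:
        empty = pd.Series(dtype=float)
        wear = steps = hr_mean = n_rec = empty

    out = pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "date": [d.date() for d in dates],
            "wear_minutes": wear.reindex(dates).fillna(0).astype(int).to_numpy(),
            "total_steps": steps.reindex(dates).fillna(0).astype(int).to_numpy(),
            "mean_hr": hr_mean.reindex(dates).to_numpy(),
            "n_records": n_rec.reindex(dates).fillna(0).astype(int).to_numpy(),
        }
    )
    out.insert(3, "wear_fraction", out["wear_minutes"] / MINUTES_PER_DAY)
    for rule in rules:
        valid = np.ones(len(out), dtype=bool)
        if rule.require_any_record:
            valid &= out["n_records"].to_numpy() > 0
        if rule.min_steps is not None:
            valid &= out["total_steps"].to_numpy() > rule.min_steps
        if rule.min_wear_fraction is not None:
            valid &= out["wear_fraction"].to_numpy() > rule.min_wear_fraction
        out[VALID_PREFIX + rule.name] = valid
    return out


def cohort_summaries(
    cohort: Cohort,
    rules: tuple[ValidDayRule, ...] = DEFAULT_RULES,
    count_steps_without_hr: bool = True,
) -> pd.DataFrame:
    """Concatenated :func:`daily_summaries` for every subject in a cohort."""
    frames = [
        daily_summaries(s, rules=rules, count_steps_without_hr=count_steps_without_hr)
        for s in cohort
    ]
    if not frames:
        raise ValueError("empty cohort")
    return pd.concat(frames, ignore_index=True)


def classify_valid_day(summary: DaySummary, rule: ValidDayRule) -> bool:
    """Apply a rule's predicate to a day summary (strict thresholds)."""
    return rule.is_valid(summary.total_steps, summary.wear_fraction, summary.n_records)


def estimate_subject(summaries: pd.DataFrame, rule: ValidDayRule) -> SubjectEstimate:
    """Average daily step count and heart rate over a rule's valid days.

    ``summaries`` holds one subject's day summaries (from
    :func:`daily_summaries`). The HR estimate is the unweighted mean of the
    daily mean HRs over valid days that have one; with zero such days the
    estimate is absent.
    """
    sids = summaries["subject_id"].unique()
    if len(sids) > 1:
        raise ValueError(f"summaries mix subjects: {list(sids)}")
    col = VALID_PREFIX + rule.name
    if col in summaries.columns:
        valid = summaries[col].to_numpy(dtype=bool)
    else:
        valid = np.array(
            [
                rule.is_valid(r.total_steps, r.wear_fraction, r.n_records)
                for r in summaries.itertuples()
            ],
            dtype=bool,
        )
    sel = summaries.loc[valid]
    n_valid = int(valid.sum())
    avg_steps = float(sel["total_steps"].mean()) if n_valid else None
    hr = sel["mean_hr"].dropna()
    avg_hr = float(hr.mean()) if len(hr) else None
    return SubjectEstimate(
        subject_id=str(sids[0]) if len(sids) else "",
        rule_name=rule.name,
        n_valid_days=n_valid,
        avg_daily_steps=avg_steps,
        avg_daily_hr=avg_hr,
    )


def subject_estimates(
    cohort: Cohort,
    rule: ValidDayRule,
    summaries: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-subject estimates under one rule, as a frame with group labels."""
    if summaries is None:
        summaries = cohort_summaries(cohort, rules=(rule,))
    group_of = cohort.group_of()
    rows = []
    for sid, sub in summaries.groupby("subject_id", sort=True):
        est = estimate_subject(sub, rule)
        rows.append(
            {
                "subject_id": sid,
                "group": group_of.get(str(sid)),
                "rule": rule.name,
                "n_valid_days": est.n_valid_days,
                "avg_daily_steps": est.avg_daily_steps,
                "avg_daily_hr": est.avg_daily_hr,
            }
        )
    return pd.DataFrame(rows)


def monthly_wear_trend(
    series: SubjectSeries, block_days: int = 30
) -> pd.DataFrame:
    """Per-month mean daily wear fraction and month-over-month change.

    Months are consecutive ``block_days``-day blocks counted from the
    study start (study lengths of 90 or 120 days tile exactly into 30-day
    blocks). The relative change from month m to m+1 is
    ``(mean_{m+1} - mean_m) / mean_m``; it is NaN for the first block and
    whenever the preceding block has zero wear. A series shorter than one
    block yields a single-block row with no change value.
    """
    summ = daily_summaries(series, rules=())
    offsets = np.array([(d - series.study_start).days for d in summ["date"]])
    block = offsets // block_days
    g = summ.groupby(block)["wear_fraction"]
    out = pd.DataFrame(
        {
            "month": g.mean().index.to_numpy() + 1,
            "n_days": g.size().to_numpy(),
            "mean_wear_fraction": g.mean().to_numpy(),
        }
    )
    prev = out["mean_wear_fraction"].shift(1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["rel_change"] = (out["mean_wear_fraction"] - prev) / prev
    out.loc[prev == 0, "rel_change"] = np.nan
    return out
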