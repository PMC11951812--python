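"""Reading and writing minute-level wearable data and derived day summaries.

The on-disk interchange format is a flat CSV with one row per subject-minute:

    subject_id,group,timestamp,heart_rate,steps

Timestamps are ISO-8601 to minute precision (``YYYY-MM-DDTHH:MM``),
timezone-naive local device time. An empty field means the value was not
registered; a minute with no row at all means neither heart rate nor steps
were registered (the device was off-wrist, or never synced). Heart-rate
presence is the wear-time signal, so the reader is deliberately strict: it
never invents rows, and duplicate subject-minutes are an error rather than
a silent merge.

Day summaries travel in a second fixed dialect (see
:data:`DAY_SUMMARY_COLUMNS`) that round-trips losslessly through
:func:`write_day_summaries` / :func:`read_day_summaries`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MINUTE_COLUMNS = ["subject_id", "group", "timestamp", "heart_rate", "steps"]
DAY_SUMMARY_COLUMNS = [
    "subject_id",
    "date",
    "wear_minutes",
    "wear_fraction",
    "total_steps",
    "mean_hr",
    "valid_none",
    "valid_stepcount1000",
    "valid_weartime80",
]

HR_MIN, HR_MAX = 25.0, 250.0
STEPS_MIN, STEPS_MAX = 0, 300

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"


class MinuteCSVError(ValueError):
    """Base class for minute-CSV format violations."""


class ParseError(MinuteCSVError):
    """A field could not be parsed; the message names the offending line."""


class IntegrityError(MinuteCSVError):
    """The file violates a structural invariant (e.g. duplicate minutes)."""


@dataclass(frozen=True)
class MinuteRecord:
    """One subject-minute: a timestamp plus optionally-registered HR and steps.

    ``heart_rate`` is in beats per minute and is present exactly when the
    device was worn that minute; ``steps`` is the step count registered for
    that minute. Either may be ``None`` (not registered).
    """

    timestamp: pd.Timestamp
    heart_rate: float | None = None
    steps: int | None = None

    def __post_init__(self) -> None:
        ts = pd.Timestamp(self.timestamp)
        if ts.second != 0 or ts.microsecond != 0 or ts.nanosecond != 0:
            raise ValueError(f"timestamp {ts} is not aligned to a minute")
        object.__setattr__(self, "timestamp", ts)
        if self.heart_rate is not None and not HR_MIN <= self.heart_rate <= HR_MAX:
            raise ValueError(f"heart_rate {self.heart_rate} outside [{HR_MIN}, {HR_MAX}]")
        if self.steps is not None and not STEPS_MIN <= self.steps <= STEPS_MAX:
            raise ValueError(f"steps {self.steps} outside [{STEPS_MIN}, {STEPS_MAX}]")


@dataclass
class SubjectSeries:
    """One subject's minute records over a study window.

    ``data`` is a DataFrame indexed by minute-resolution timestamps with
    float columns ``heart_rate`` and ``steps``; ``NaN`` encodes "not
    registered". Minutes with no row are simply absent from the index.
    """

    subject_id: str
    group: str
    data: pd.DataFrame
    study_start: date
    study_end: date

    def __post_init__(self) -> None:
        if self.study_end < self.study_start:
            raise ValueError("study_end precedes study_start")
        df = self.data
        if list(df.columns) != ["heart_rate", "steps"]:
            df = df[["heart_rate", "steps"]]
        if not isinstance(df.index, pd.DatetimeIndex):
            df = df.set_axis(pd.DatetimeIndex(df.index))
        if len(df) > 0:
            if not df.index.is_monotonic_increasing:
                df = df.sort_index()
            if df.index.has_duplicates:
                dup = df.index[df.index.duplicated()][0]
                raise IntegrityError(
                    f"subject {self.subject_id!r}: duplicate minute {dup}"
                )
            if (df.index.second != 0).any() or (df.index.microsecond != 0).any():
                raise ValueError("timestamps must be minute-aligned")
            lo, hi = df.index[0].date(), df.index[-1].date()
            if lo < self.study_start or hi > self.study_end:
                raise ValueError(
                    f"subject {self.subject_id!r}: records span [{lo}, {hi}], "
                    f"outside study window [{self.study_start}, {self.study_end}]"
                )
        self.data = df.astype({"heart_rate": float, "steps": float})

    @property
    def n_study_days(self) -> int:
        return (self.study_end - self.study_start).days + 1

    def study_dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.study_start, self.study_end, freq="D")

    def iter_records(self) -> Iterator[MinuteRecord]:
        for ts, hr, steps in self.data.itertuples():
            yield MinuteRecord(
                timestamp=ts,
                heart_rate=None if pd.isna(hr) else float(hr),
                steps=None if pd.isna(steps) else int(steps),
            )

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Cohort:
    """A collection of subjects with unique ids, each labelled with a group."""

    subjects: list[SubjectSeries] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise IntegrityError(f"duplicate subject_id {dup!r}")

    def __iter__(self) -> Iterator[SubjectSeries]:
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    def __getitem__(self, subject_id: str) -> SubjectSeries:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    @property
    def groups(self) -> list[str]:
        out: list[str] = []
        for s in self.subjects:
            if s.group not in out:
                out.append(s.group)
        return out

    def group_of(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.subjects}


def read_minute_csv(
    path,
    study_window: tuple[date, date] | None = None,
) -> Cohort:
    """Read a minute CSV into a :class:`Cohort`.

    Parameters
    ----------
    path
        CSV file in the minute dialect (see module docstring).
    study_window
        ``(start_date, end_date)`` applied to every subject. When omitted,
        each subject's window is the span of its own records.

    Notes
    -----
    A heart rate of 0 is treated as sensor dropout and converted to
    "absent", with a logged warning; steps may legitimately be present in
    minutes without heart rate and are preserved as such.
    """
    df = pd.read_csv(
        path,
        dtype={"subject_id": str, "group": str, "timestamp": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in MINUTE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")
    if len(df) == 0:
        return Cohort([])

    ts = pd.to_datetime(df["timestamp"], format=TIMESTAMP_FORMAT, errors="coerce")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        # +2: 1-based and one header line
        raise ParseError(
            f"line {bad + 2}: malformed timestamp {df['timestamp'].iloc[bad]!r}"
        )
    df = df.assign(timestamp=ts)

    hr = pd.to_numeric(df["heart_rate"], errors="coerce")
    n_zero = int((hr == 0).sum())
    if n_zero:
        logger.warning("%d heart_rate=0 values treated as absent (sensor dropout)", n_zero)
        hr = hr.mask(hr == 0)
    steps = pd.to_numeric(df["steps"], errors="coerce")
    df = df.assign(heart_rate=hr, steps=steps)

    dup = df.duplicated(subset=["subject_id", "timestamp"])
    if dup.any():
        row = df.loc[dup].iloc[0]
        raise IntegrityError(
            f"duplicate subject-minute: {row['subject_id']!r} at "
            f"{row['timestamp'].strftime(TIMESTAMP_FORMAT)}"
        )

    subjects: list[SubjectSeries] = []
    for sid, sub in df.groupby("subject_id", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 1:
            raise IntegrityError(f"subject {sid!r} has multiple groups: {list(groups)}")
        data = sub.set_index("timestamp")[["heart_rate", "steps"]].sort_index()
        if study_window is not None:
            start, end = study_window
        else:
            start, end = data.index[0].date(), data.index[-1].date()
        subjects.append(
            SubjectSeries(
                subject_id=str(sid),
                group=str(groups[0]),
                data=data,
                study_start=start,
                study_end=end,
            )
        )
    return Cohort(subjects)


def _fmt_hr(v: float) -> str:
    if pd.isna(v):
        return ""
    return f"{v:g}"


def _fmt_steps(v: float) -> str:
    if pd.isna(v):
        return ""
    return str(int(v))


def write_minute_csv(cohort: Cohort | Iterable[SubjectSeries], path) -> None:
    """Write a cohort in the minute CSV dialect (sorted, deterministic)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(MINUTE_COLUMNS) + "\n")
        for series in cohort:
            sid, grp = series.subject_id, series.group
            for ts, hr, steps in series.data.itertuples():
                fh.write(
                    f"{sid},{grp},{ts.strftime(TIMESTAMP_FORMAT)},"
                    f"{_fmt_hr(hr)},{_fmt_steps(steps)}\n"
                )


def write_day_summaries(path, summaries: pd.DataFrame) -> None:
    """Write per-day summaries in the fixed day-summary dialect.

    ``summaries`` must have the columns in :data:`DAY_SUMMARY_COLUMNS`.
    ``wear_fraction`` and ``mean_hr`` are serialized with fixed 6-decimal
    precision; an absent ``mean_hr`` serializes to the empty string.
    """
    if len(summaries) == 0:
        raise ValueError("refusing to write an empty day-summary collection")
    missing = [c for c in DAY_SUMMARY_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"day summaries missing columns: {missing}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(DAY_SUMMARY_COLUMNS) + "\n")
        for row in summaries[DAY_SUMMARY_COLUMNS].itertuples(index=False):
            d = row.date
            if isinstance(d, (pd.Timestamp, datetime)):
                d = d.date()
            mean_hr = "" if pd.isna(row.mean_hr) else f"{row.mean_hr:.6f}"
            fh.write(
                f"{row.subject_id},{d.isoformat()},{int(row.wear_minutes)},"
                f"{row.wear_fraction:.6f},{int(row.total_steps)},{mean_hr},"
                f"{bool(row.valid_none)},{bool(row.valid_stepcount1000)},"
                f"{bool(row.valid_weartime80)}\n"
            )


def read_day_summaries(path) -> pd.DataFrame:
    """Read day summaries written by :func:`write_day_summaries`."""
    df = pd.read_csv(
        path,
        dtype={"subject_id": str},
        keep_default_na=False,
        na_values=[""],
    )
    missing = [c for c in DAY_SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"day-summary file missing columns: {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    for col in ("valid_none", "valid_stepcount1000", "valid_weartime80"):
        df[col] = df[col].map({"True": True, "False": False, True: True, False: False})
    df["wear_minutes"] = df["wear_minutes"].astype(int)
    df["total_steps"] = df["total_steps"].astype(int)
    df["wear_fraction"] = df["wear_fraction"].astype(float)
    df["mean_hr"] = pd.to_numeric(df["mean_hr"], errors="coerce")
    return df
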