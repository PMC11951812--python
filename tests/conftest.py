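"""Shared builders for compact, fully specified subject series."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from weartime.io import Cohort, SubjectSeries

START = date(2021, 1, 1)


def make_series(
    minutes,
    subject_id: str = "s1",
    group: str = "g1",
    study_start: date = START,
    study_days: int | None = None,
) -> SubjectSeries:
    """Build a series from (timestamp-string, hr, steps) triples.

    ``hr``/``steps`` of ``None`` mean "not registered"; the study window
    defaults to the span of the records.
    """
    ts = pd.DatetimeIndex([pd.Timestamp(t) for t, _, _ in minutes])
    data = pd.DataFrame(
        {
            "heart_rate": [np.nan if h is None else float(h) for _, h, _ in minutes],
            "steps": [np.nan if s is None else float(s) for _, _, s in minutes],
        },
        index=ts,
    )
    if study_days is not None:
        end = study_start + timedelta(days=study_days - 1)
    elif len(ts):
        study_start = min(study_start, ts.min().date())
        end = ts.max().date()
    else:
        end = study_start
    return SubjectSeries(subject_id, group, data, study_start, end)


def series_from_daily(
    wear_minutes_per_day,
    steps_per_worn_minute: int = 1,
    hr: float = 70.0,
    subject_id: str = "s1",
    group: str = "g1",
    study_start: date = START,
) -> SubjectSeries:
    """A subject wearing the device for the first N minutes of each day."""
    frames = []
    for d, w in enumerate(wear_minutes_per_day):
        if w == 0:
            continue
        day_start = pd.Timestamp(study_start) + pd.Timedelta(days=d)
        idx = day_start + pd.to_timedelta(np.arange(w), unit="m")
        frames.append(
            pd.DataFrame(
                {"heart_rate": hr, "steps": float(steps_per_worn_minute)}, index=idx
            )
        )
    if frames:
        data = pd.concat(frames)
    else:
        data = pd.DataFrame(
            {"heart_rate": pd.Series(dtype=float), "steps": pd.Series(dtype=float)}
        )
    end = study_start + timedelta(days=len(wear_minutes_per_day) - 1)
    return SubjectSeries(subject_id, group, data, study_start, end)


def random_series(
    rng: np.random.Generator,
    study_days: int = 3,
    subject_id: str = "s1",
    group: str = "g1",
) -> SubjectSeries:
    """A random sparse series: random worn minutes, random HR/steps gaps."""
    total = study_days * 1440
    n = int(rng.integers(1, total // 2))
    offsets = np.sort(rng.choice(total, size=n, replace=False))
    idx = pd.Timestamp(START) + pd.to_timedelta(offsets, unit="m")
    hr = rng.uniform(40, 180, size=n)
    hr[rng.random(n) < 0.3] = np.nan
    steps = rng.integers(0, 200, size=n).astype(float)
    steps[rng.random(n) < 0.3] = np.nan
    data = pd.DataFrame({"heart_rate": hr, "steps": steps}, index=idx)
    return SubjectSeries(
        subject_id, group, data, START, START + timedelta(days=study_days - 1)
    )


@pytest.fixture
def toy_cohort() -> Cohort:
    """Three subjects: fully compliant, morning-only wearer, never-worn."""
    full = series_from_daily([1440] * 3, steps_per_worn_minute=6, subject_id="full")
    # worn 08:00-10:00 only, walking the whole time
    morning_rows = []
    for d in range(3):
        day = pd.Timestamp(START) + pd.Timedelta(days=d)
        for m in range(480, 600):
            morning_rows.append((day + pd.Timedelta(minutes=m), 95.0, 85))
    morning = make_series(
        [(t, h, s) for t, h, s in morning_rows],
        subject_id="morning",
        study_days=3,
    )
    never = make_series([], subject_id="never", study_days=3)
    return Cohort([full, morning, never])
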