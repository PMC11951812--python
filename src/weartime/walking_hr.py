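"""Walking heart rate: cadence-gated sampling and SE convergence.

A minute with a high step count (cadence at or above ~80 steps/min) very
likely belongs to a walking bout, so the heart-rate values registered in
such minutes form a sample of "walking heart rate". Unlike a daily
average, this estimand does not need whole days of wear — it needs enough
walking minutes, whenever they occur. The question "how many?" is answered
empirically: the standard error of the mean is evaluated on random
subsamples of increasing size, and convergence is declared at the smallest
size from which the mean SE stays at or below a bpm threshold (1 bpm by
default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import PRESET_RULES, ValidDayRule, daily_summaries, estimate_subject
from .io import SubjectSeries

DEFAULT_CADENCE_THRESHOLD = 80
DEFAULT_SE_THRESHOLD = 1.0  # bpm
DEFAULT_REPETITIONS = 100
DEFAULT_GRID_STEP = 10

FEASIBILITY_LABELS = ("both", "walking_only", "steps_only", "neither")


@dataclass(frozen=True)
class WalkingSamples:
    """Heart-rate samples taken in a subject's walking minutes.

    ``samples`` has a minute timestamp index and a ``heart_rate`` column;
    ``n_missing_hr`` counts walking-cadence minutes that had to be dropped
    because no heart rate was registered there.
    """

    subject_id: str
    samples: pd.DataFrame
    cadence_threshold: float
    inclusive: bool
    n_missing_hr: int

    @property
    def heart_rates(self) -> np.ndarray:
        return self.samples["heart_rate"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class ConvergenceTrace:
    """Mean subsample SE (bpm) on a grid of subsample sizes."""

    n: np.ndarray
    mean_se: np.ndarray
    repetitions: int
    seed: int | None

    def __post_init__(self) -> None:
        n = np.asarray(self.n)
        if len(n) == 0:
            raise ValueError("empty grid")
        if not (np.diff(n) > 0).all():
            raise ValueError("grid must be strictly increasing")
        if (np.asarray(self.mean_se) < 0).any():
            raise ValueError("SE values must be non-negative")


@dataclass(frozen=True)
class FeasibilityLabel:
    """Which research questions a subject's data can answer.

    ``steps`` requires at least one valid day under the reference rule;
    ``walking hr`` requires SE convergence of the walking-HR samples.
    """

    subject_id: str
    has_step_estimate: bool
    has_walking_hr: bool
    label: str
    n_walking_minutes: int
    n_required: int | None
    days_to_reach: int | None
    walking_hr_mean: float | None

    def __post_init__(self) -> None:
        expected = {
            (True, True): "both",
            (True, False): "steps_only",
            (False, True): "walking_only",
            (False, False): "neither",
        }[(self.has_step_estimate, self.has_walking_hr)]
        if self.label != expected:
            raise ValueError(f"label {self.label!r} inconsistent with flags")


def extract_walking_minutes(
    series: SubjectSeries,
    cadence_threshold: float = DEFAULT_CADENCE_THRESHOLD,
    inclusive: bool = True,
) -> WalkingSamples:
    """Isolate heart-rate samples from minutes at walking cadence.

    A walking minute has a registered step count at or above the cadence
    threshold (``inclusive=False`` switches to a strict ``>``). Walking
    minutes without a registered heart rate yield no sample and are
    counted in ``n_missing_hr``.
    """
    if cadence_threshold <= 0:
        raise ValueError("cadence threshold must be positive")
    df = series.data
    steps = df["steps"]
    fast = steps >= cadence_threshold if inclusive else steps > cadence_threshold
    fast = fast.fillna(False)
    has_hr = df["heart_rate"].notna()
    samples = df.loc[fast & has_hr, ["heart_rate"]].copy()
    return WalkingSamples(
        subject_id=series.subject_id,
        samples=samples,
        cadence_threshold=cadence_threshold,
        inclusive=inclusive,
        n_missing_hr=int((fast & ~has_hr).sum()),
    )


def standard_error(values: Sequence[float]) -> float:
    """SE of the mean: sample standard deviation (n-1) over sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("standard error needs at least 2 values")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def default_grid(n_total: int, step: int = DEFAULT_GRID_STEP) -> np.ndarray:
    """Subsample-size grid from ``step`` to the full sample in ``step``s."""
    if n_total < 2:
        raise ValueError("need at least 2 samples")
    start = min(step, n_total)
    start = max(start, 2)
    grid = np.arange(start, n_total + 1, step)
    if len(grid) == 0 or grid[-1] != n_total:
        grid = np.append(grid, n_total)
    return grid


def convergence_curve(
    values: Sequence[float],
    n_grid: Sequence[int] | None = None,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int | np.random.Generator | None = None,
) -> ConvergenceTrace:
    """Mean SE over random subsamples for an increasing number of samples.

    For each repetition one uniform random permutation of the values is
    drawn; its length-n prefixes are uniform without-replacement subsamples
    of every grid size n, so each grid point sees ``repetitions``
    independent-across-repetitions subsamples while a repetition costs a
    single O(N) pass (prefix sums). The trace is deterministic for a fixed
    seed; at n equal to the full sample size the SE is exact.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    grid = default_grid(x.size) if n_grid is None else np.asarray(sorted(n_grid))
    if grid[0] < 2:
        raise ValueError("grid sizes must be >= 2")
    if grid[-1] > x.size:
        raise ValueError(f"grid max {grid[-1]} exceeds sample count {x.size}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    acc = np.zeros(len(grid))
    idx = grid - 1
    for _ in range(repetitions):
        perm = rng.permutation(x)
        cs = np.cumsum(perm)
        cs2 = np.cumsum(perm * perm)
        n = grid.astype(float)
        var = (cs2[idx] - cs[idx] ** 2 / n) / (n - 1)
        np.maximum(var, 0.0, out=var)
        acc += np.sqrt(var) / np.sqrt(n)
    return ConvergenceTrace(
        n=grid,
        mean_se=acc / repetitions,
        repetitions=repetitions,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def min_samples_for_convergence(
    trace: ConvergenceTrace, threshold: float = DEFAULT_SE_THRESHOLD
) -> int | None:
    """Smallest grid size from which the mean SE stays at or below threshold.

    The crossing must be sustained: the returned n and every larger grid n
    satisfy ``mean SE <= threshold``. Returns ``None`` when the curve never
    settles below the threshold (not converged).
    """
    below = np.asarray(trace.mean_se) <= threshold
    if not below[-1]:
        return None
    above = np.flatnonzero(~below)
    if len(above) == 0:
        return int(trace.n[0])
    return int(trace.n[above[-1] + 1])


def days_to_reach(
    series: SubjectSeries,
    n_required: int,
    cadence_threshold: float = DEFAULT_CADENCE_THRESHOLD,
    inclusive: bool = True,
) -> int | None:
    """1-based study day on which cumulative walking minutes reach a target.

    Walking minutes accumulate in chronological order from the study start;
    returns ``None`` when the subject never accumulates ``n_required``.
    """
    if n_required < 1:
        raise ValueError("n_required must be >= 1")
    ws = extract_walking_minutes(series, cadence_threshold, inclusive)
    if len(ws) < n_required:
        return None
    nth = ws.samples.index[n_required - 1]
    return (nth.date() - series.study_start).days + 1


def classify_feasibility(
    series: SubjectSeries,
    reference_rule: ValidDayRule | None = None,
    cadence_threshold: float = DEFAULT_CADENCE_THRESHOLD,
    inclusive: bool = True,
    se_threshold: float = DEFAULT_SE_THRESHOLD,
    repetitions: int = DEFAULT_REPETITIONS,
    seed: int | np.random.Generator | None = None,
    summaries: pd.DataFrame | None = None,
) -> FeasibilityLabel:
    """Label which of the two research questions a subject can support.

    The daily-step question needs >= 1 valid day under the reference rule
    (wear time > 80% by default); the walking-HR question needs the
    subsample SE curve to converge below ``se_threshold``. The four labels
    are ``both``, ``steps_only``, ``walking_only``, ``neither`` — a
    low-compliance subject with many walking bouts is the archetypal
    ``walking_only`` case.
    """
    rule = PRESET_RULES["weartime80"] if reference_rule is None else reference_rule
    if summaries is None:
        summaries = daily_summaries(series, rules=(rule,))
    est = estimate_subject(summaries, rule)
    has_steps = est.n_valid_days >= 1

    ws = extract_walking_minutes(series, cadence_threshold, inclusive)
    n_required: int | None = None
    reach: int | None = None
    hr_mean: float | None = None
    has_walking = False
    if len(ws) >= 2:
        trace = convergence_curve(ws.heart_rates, repetitions=repetitions, seed=seed)
        n_required = min_samples_for_convergence(trace, se_threshold)
        if n_required is not None:
            has_walking = True
            hr_mean = float(ws.heart_rates.mean())
            reach = days_to_reach(series, n_required, cadence_threshold, inclusive)
    label = {
        (True, True): "both",
        (True, False): "steps_only",
        (False, True): "walking_only",
        (False, False): "neither",
    }[(has_steps, has_walking)]
    return FeasibilityLabel(
        subject_id=series.subject_id,
        has_step_estimate=has_steps,
        has_walking_hr=has_walking,
        label=label,
        n_walking_minutes=len(ws),
        n_required=n_required,
        days_to_reach=reach,
        walking_hr_mean=hr_mean,
    )
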