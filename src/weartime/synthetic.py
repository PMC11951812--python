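"""Synthetic minute-level wearable cohorts with ground truth.

The study's Fitbit exports are not public, so the analyses are exercised
on simulated cohorts that reproduce the statistical structure they rely
on:

* a per-minute wear indicator with a diurnal profile (little overnight
  wear for partial wearers), day-to-day variability, geometric monthly
  decay of the wear target (wearables abandonment) and a per-subject
  probability of never wearing the device at all;
* walking bouts (Poisson count per day, random daytime placement, minute
  cadence around ~105 steps/min) over a low background step rate, giving
  realistic daily totals;
* heart rate present exactly in worn minutes, equal to a per-subject
  resting baseline plus a per-bout walking elevation plus minute noise;
* optional wear–activity coupling: with a positive coefficient, wear is
  more likely during walking bouts, breaking the missing-at-random
  assumption and biasing naive (no wear-time filtering) step estimates.

Steps are registered only while the device is worn; the ground truth kept
alongside each subject records what a fully worn device would have seen,
so estimator bias is scoreable exactly.

All randomness flows from one master seed: subject (group_index,
subject_index) pairs become ``numpy.random.SeedSequence(master_seed,
spawn_key=(group_index, subject_index))`` streams, so any single subject
can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .core import MINUTES_PER_DAY
from .io import Cohort, SubjectSeries, write_minute_csv

TRUTH_COLUMNS = [
    "subject_id",
    "group",
    "true_daily_steps",
    "true_walking_hr",
    "resting_hr",
    "wear_target_hours",
    "monthly_decay",
    "coupling",
    "never_wore",
]

# Hourly wear propensity: near-zero overnight, flat through the day with an
# evening shoulder — a partial wearer looks like a daytime-only wearer.
DEFAULT_DIURNAL_WEIGHTS: tuple[float, ...] = (
    0.15, 0.10, 0.10, 0.10, 0.10, 0.20,  # 00-05
    0.60, 1.00, 1.00, 1.00, 1.00, 1.00,  # 06-11
    1.00, 1.00, 1.00, 1.00, 1.00, 1.00,  # 12-17
    1.00, 1.00, 0.90, 0.70, 0.45, 0.25,  # 18-23
)


@dataclass(frozen=True)
class WearModel:
    """Wear-indicator model for one group.

    ``target_hours`` is the group's average daily wear before decay;
    ``monthly_decay`` shrinks the target geometrically every 30 days;
    ``day_concentration`` is the Beta concentration of day-to-day wear
    variability (smaller = wilder days, with mass near 0 for low targets);
    ``never_wear_prob`` is the chance a subject receives the device and
    never wears it.
    """

    target_hours: float = 16.0
    diurnal_weights: tuple[float, ...] = DEFAULT_DIURNAL_WEIGHTS
    monthly_decay: float = 0.10
    never_wear_prob: float = 0.0
    day_concentration: float = 6.0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_hours <= 24.0:
            raise ValueError("target_hours must be in (0, 24]")
        if not 0.0 <= self.monthly_decay <= 1.0:
            raise ValueError("monthly_decay must be in [0, 1]")
        if not 0.0 <= self.never_wear_prob <= 1.0:
            raise ValueError("never_wear_prob must be in [0, 1]")
        if len(self.diurnal_weights) != 24:
            raise ValueError("diurnal_weights needs 24 hourly values")
        if min(self.diurnal_weights) < 0 or sum(self.diurnal_weights) == 0:
            raise ValueError("diurnal_weights must be non-negative, not all zero")
        if self.day_concentration <= 0:
            raise ValueError("day_concentration must be positive")


@dataclass(frozen=True)
class ActivityModel:
    """Step-generation model: walking bouts over a background rate.

    Walking bouts per day are Poisson(``bouts_per_day``); each bout lasts
    ``1 + Poisson(mean_bout_minutes - 1)`` minutes with per-minute cadence
    Normal(``cadence_mean``, ``cadence_sd``) truncated to [1, 300] steps.
    Non-bout minutes inside the awake window carry Poisson background
    steps (fidgeting, short trips).
    """

    bouts_per_day: float = 6.0
    mean_bout_minutes: float = 10.0
    cadence_mean: float = 105.0
    cadence_sd: float = 10.0
    background_step_rate: float = 1.5
    awake_start_hour: int = 7
    awake_end_hour: int = 22

    def __post_init__(self) -> None:
        if self.bouts_per_day < 0 or self.background_step_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.mean_bout_minutes < 1:
            raise ValueError("mean_bout_minutes must be >= 1")
        if not 0 <= self.awake_start_hour < self.awake_end_hour <= 24:
            raise ValueError("awake window must satisfy 0 <= start < end <= 24")


@dataclass(frozen=True)
class HRModel:
    """Heart-rate model: resting baseline + walking elevation + noise.

    A subject's resting HR is Normal(``resting_mean``, ``resting_sd``);
    walking minutes add a per-bout elevation Normal(``walking_elevation``,
    ``bout_elevation_sd``) — bouts differ in pace, grade and time of day —
    plus minute-level noise with sd ``minute_noise_sd``. All units bpm.
    """

    resting_mean: float = 65.0
    resting_sd: float = 5.0
    walking_elevation: float = 40.0
    bout_elevation_sd: float = 14.0
    minute_noise_sd: float = 10.0

    def __post_init__(self) -> None:
        for v in (self.resting_sd, self.bout_elevation_sd, self.minute_noise_sd):
            if v < 0:
                raise ValueError("standard deviations must be non-negative")


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Full generator configuration for one group.

    ``coupling`` >= 0 multiplies the per-minute wear probability by
    ``1 + coupling`` during walking bouts (capped at 1); 0 keeps wear
    missing-at-random with respect to activity.
    """

    n_subjects: int = 12
    study_days: int = 90
    wear: WearModel = field(default_factory=WearModel)
    activity: ActivityModel = field(default_factory=ActivityModel)
    hr: HRModel = field(default_factory=HRModel)
    coupling: float = 0.0
    study_start: date = date(2021, 1, 1)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.study_days < 30:
            raise ValueError("study_days must be >= 30")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")


@dataclass(frozen=True)
class SyntheticTruth:
    """Generator ground truth for one subject.

    ``true_daily_steps`` is the realized mean daily step total a fully
    worn device would have registered; ``true_walking_hr`` is the
    subject's walking-HR mean parameter (resting + mean elevation).
    """

    subject_id: str
    group: str
    true_daily_steps: float
    true_walking_hr: float
    resting_hr: float
    wear_target_hours: float
    monthly_decay: float
    coupling: float
    never_wore: bool


def subject_stream(master_seed: int, group_index: int, subject_index: int) -> np.random.Generator:
    """The documented seed derivation: one independent stream per subject."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(group_index, subject_index))
    return np.random.default_rng(ss)


def _hourly_wear_probs(weights: np.ndarray, fraction: float) -> np.ndarray:
    """Per-hour wear probabilities proportional to weights, water-filled.

    Scales weights so the expected worn minutes equal ``fraction * 1440``;
    hours that would exceed probability 1 are capped and the excess is
    redistributed over the remaining hours.
    """
    w = np.asarray(weights, dtype=float)
    p = np.zeros(24)
    if fraction <= 0:
        return p
    if fraction >= 1:
        return np.ones(24)
    remaining = fraction * MINUTES_PER_DAY
    active = w > 0
    for _ in range(24):
        denom = 60.0 * w[active].sum()
        if denom == 0:
            break
        scale = remaining / denom
        p[active] = scale * w[active]
        over = active & (p >= 1.0)
        if not over.any():
            break
        p[over] = 1.0
        remaining -= 60.0 * over.sum()
        active &= ~over
        if remaining <= 0:
            break
    return np.clip(p, 0.0, 1.0)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, size: int,
                      lo: float, hi: float) -> np.ndarray:
    x = rng.normal(mean, sd, size)
    return np.clip(x, lo, hi)


def generate_subject(
    config: SyntheticCohortConfig,
    subject_id: str,
    group: str,
    rng: np.random.Generator | int,
) -> tuple[SubjectSeries, SyntheticTruth]:
    """Simulate one subject's minute series plus its ground truth.

    The activity schedule (every minute's true step count) is drawn first,
    independent of wear; the wear mask is then applied, and only worn
    minutes produce CSV rows (HR present iff worn). Deterministic for a
    fixed generator state.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    days = config.study_days
    total = days * MINUTES_PER_DAY
    act, hrm, wm = config.activity, config.hr, config.wear

    resting = float(rng.normal(hrm.resting_mean, hrm.resting_sd))
    never = bool(rng.random() < wm.never_wear_prob)

    # --- activity schedule under full wear -------------------------------
    steps_true = np.zeros(total, dtype=np.int64)
    elevation = np.zeros(total)
    is_bout = np.zeros(total, dtype=bool)
    awake_lo = act.awake_start_hour * 60
    awake_hi = act.awake_end_hour * 60

    n_bouts = rng.poisson(act.bouts_per_day, size=days)
    for d in range(days):
        base = d * MINUTES_PER_DAY
        for _ in range(n_bouts[d]):
            length = 1 + int(rng.poisson(max(act.mean_bout_minutes - 1, 0)))
            start = int(rng.integers(awake_lo, max(awake_hi - length, awake_lo + 1)))
            sl = slice(base + start, min(base + start + length, base + MINUTES_PER_DAY))
            n = sl.stop - sl.start
            cadence = _truncated_normal(rng, act.cadence_mean, act.cadence_sd, n, 1, 300)
            steps_true[sl] = np.round(cadence).astype(np.int64)
            elevation[sl] = rng.normal(hrm.walking_elevation, hrm.bout_elevation_sd)
            is_bout[sl] = True

    minute_of_day = np.tile(np.arange(MINUTES_PER_DAY), days)
    awake = (minute_of_day >= awake_lo) & (minute_of_day < awake_hi)
    background = awake & ~is_bout
    if act.background_step_rate > 0:
        steps_true[background] = rng.poisson(
            act.background_step_rate, size=int(background.sum())
        )
    np.clip(steps_true, 0, 300, out=steps_true)

    true_daily_steps = float(steps_true.reshape(days, MINUTES_PER_DAY).sum(axis=1).mean())
    truth = SyntheticTruth(
        subject_id=subject_id,
        group=group,
        true_daily_steps=true_daily_steps,
        true_walking_hr=resting + hrm.walking_elevation,
        resting_hr=resting,
        wear_target_hours=wm.target_hours,
        monthly_decay=wm.monthly_decay,
        coupling=config.coupling,
        never_wore=never,
    )

    if never:
        empty = pd.DataFrame(
            {"heart_rate": pd.Series(dtype=float), "steps": pd.Series(dtype=float)},
            index=pd.DatetimeIndex([], name="timestamp"),
        )
        series = SubjectSeries(
            subject_id=subject_id,
            group=group,
            data=empty,
            study_start=config.study_start,
            study_end=config.study_start + timedelta(days=days - 1),
        )
        return series, truth

    # --- wear mask -------------------------------------------------------
    base_fraction = min(wm.target_hours / 24.0, 1.0)
    month = np.arange(days) // 30
    day_target = base_fraction * (1.0 - wm.monthly_decay) ** month
    kappa = wm.day_concentration
    day_fraction = np.empty(days)
    for d in range(days):
        m = day_target[d]
        if m >= 1.0:
            day_fraction[d] = 1.0
        elif m <= 0.0:
            day_fraction[d] = 0.0
        else:
            day_fraction[d] = rng.beta(kappa * m, kappa * (1.0 - m))

    weights = np.asarray(wm.diurnal_weights, dtype=float)
    p = np.empty(total)
    for d in range(days):
        hourly = _hourly_wear_probs(weights, day_fraction[d])
        p[d * MINUTES_PER_DAY : (d + 1) * MINUTES_PER_DAY] = np.repeat(hourly, 60)
    if config.coupling > 0:
        p[is_bout] = np.minimum(1.0, p[is_bout] * (1.0 + config.coupling))
    worn = rng.random(total) < p

    # --- registered signal ----------------------------------------------
    hr = resting + elevation + rng.normal(0.0, hrm.minute_noise_sd, size=total)
    hr = np.clip(np.round(hr), 25, 250)

    idx_worn = np.flatnonzero(worn)
    start_ts = pd.Timestamp(config.study_start)
    timestamps = start_ts + pd.to_timedelta(idx_worn, unit="m")
    data = pd.DataFrame(
        {
            "heart_rate": hr[idx_worn].astype(float),
            "steps": steps_true[idx_worn].astype(float),
        },
        index=pd.DatetimeIndex(timestamps, name="timestamp"),
    )
    series = SubjectSeries(
        subject_id=subject_id,
        group=group,
        data=data,
        study_start=config.study_start,
        study_end=config.study_start + timedelta(days=days - 1),
    )
    return series, truth


def generate_cohort(
    configs: Mapping[str, SyntheticCohortConfig],
    master_seed: int,
    out_dir=None,
) -> tuple[Cohort, pd.DataFrame]:
    """Simulate every group; optionally write minute CSV + truth table.

    Subject seeds are derived deterministically from ``master_seed`` (see
    :func:`subject_stream`), so the same seed yields byte-identical CSV
    output. Returns the in-memory cohort and the truth table.
    """
    if len(configs) == 0:
        raise ValueError("empty group configuration")
    names = list(configs)
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names")

    subjects = []
    truths = []
    for gi, (group, cfg) in enumerate(configs.items()):
        for si in range(cfg.n_subjects):
            sid = f"{group}_{si:03d}"
            rng = subject_stream(master_seed, gi, si)
            series, truth = generate_subject(cfg, sid, group, rng)
            subjects.append(series)
            truths.append(asdict(truth))
    cohort = Cohort(subjects)
    truth_df = pd.DataFrame(truths, columns=TRUTH_COLUMNS)

    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        write_minute_csv(cohort, os.path.join(out_dir, "minute.csv"))
        write_truth(truth_df, os.path.join(out_dir, "truth.csv"))
    return cohort, truth_df


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the ground-truth table (fixed column order, 6-decimal floats)."""
    out = truth[TRUTH_COLUMNS].copy()
    out.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str, "group": str})
    return df


def default_study_configs(
    n_subjects: int = 12, coupling: float = 0.0
) -> dict[str, SyntheticCohortConfig]:
    """Six groups emulating the study's cohorts.

    Wear targets span 20.8 h/day (transplant caregivers, the most
    compliant) down to 9.8 h/day (pediatric oncology patients, the least),
    with monthly decay from 8% to 19% and a nonzero never-wear probability
    for the student and pediatric-oncology groups; the oncology groups run
    120 study days, the others 90.
    """

    def cfg(hours, decay, never, days):
        return SyntheticCohortConfig(
            n_subjects=n_subjects,
            study_days=days,
            wear=WearModel(
                target_hours=hours, monthly_decay=decay, never_wear_prob=never
            ),
            coupling=coupling,
        )

    return {
        "hct_caregivers": cfg(20.8, 0.08, 0.0, 90),
        "hd_caregivers": cfg(19.0, 0.10, 0.0, 90),
        "sci_caregivers": cfg(18.0, 0.11, 0.0, 90),
        "students": cfg(14.0, 0.12, 0.05, 90),
        "onc_caregivers": cfg(13.0, 0.12, 0.05, 120),
        "onc_patients": cfg(9.8, 0.19, 0.07, 120),
    }


def recovery_score(
    estimates: pd.DataFrame,
    truth: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score estimates against generator truth: bias and RMSE per rule.

    ``estimates`` needs columns ``subject_id``, ``rule``,
    ``avg_daily_steps`` and optionally ``walking_hr_mean``; ``truth`` is
    the generator's table. Bias is estimate minus truth. Returns
    (per-subject frame, per-rule aggregate frame); never-worn subjects or
    subjects without an estimate under a rule contribute NaN bias and are
    excluded from aggregates.
    """
    required = {"subject_id", "rule", "avg_daily_steps"}
    if not required <= set(estimates.columns):
        raise ValueError(f"estimates need columns {sorted(required)}")
    unknown = set(estimates["subject_id"]) - set(truth["subject_id"])
    if unknown:
        raise ValueError(f"estimates reference unknown subjects: {sorted(unknown)[:5]}")

    t = truth.set_index("subject_id")
    per = estimates.copy()
    per["true_daily_steps"] = per["subject_id"].map(t["true_daily_steps"])
    per["bias_steps"] = per["avg_daily_steps"] - per["true_daily_steps"]
    if "walking_hr_mean" in per.columns:
        per["true_walking_hr"] = per["subject_id"].map(t["true_walking_hr"])
        per["bias_walking_hr"] = per["walking_hr_mean"] - per["true_walking_hr"]

    rows = []
    for rule, sub in per.groupby("rule", sort=True):
        b = sub["bias_steps"].dropna()
        row = {
            "rule": rule,
            "n_scored": int(b.size),
            "mean_bias_steps": float(b.mean()) if b.size else np.nan,
            "rmse_steps": float(np.sqrt((b**2).mean())) if b.size else np.nan,
        }
        if "bias_walking_hr" in sub.columns:
            bh = sub["bias_walking_hr"].dropna()
            row["mean_bias_walking_hr"] = float(bh.mean()) if bh.size else np.nan
            row["rmse_walking_hr"] = float(np.sqrt((bh**2).mean())) if bh.size else np.nan
        rows.append(row)
    return per, pd.DataFrame(rows)
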