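# Methods

## Wear time and day summaries

Wear time over a window is the count of minutes with a registered
heart-rate value divided by the window length in minutes. This leans on
one device property: consumer wrist wearables register a per-minute HR
value exactly while worn. Days are local calendar dates
(midnight-to-midnight, timezone-naive device time, no DST handling), and
the daily denominator is always 1440 — partial first/last study days are
kept as ordinary days rather than rescaled, which keeps the wear-time
definition literal and comparable across days.

Steps registered in minutes without a heart-rate value count toward the
daily step total (they were registered) but never toward wear minutes
(wear is defined by HR presence alone). Whether such minutes occur in
real exports is device-dependent, so `count_steps_without_hr` is a
switch; the synthetic generator itself never produces them. A heart rate
of exactly 0 in an input file is treated as sensor dropout (absent) with
a logged warning — 0 bpm is not a physiological value.

## Valid-day rules and estimates

A rule holds an optional step floor and an optional wear-fraction floor;
both thresholds are strict (`>`), so a day with exactly 1000 steps or
exactly 80% wear is invalid under the respective preset. The `none` rule
keeps every study day, including days with no records at all: a
received-but-never-worn device legitimately contributes 0-step days to a
naive analysis, which is precisely the failure mode the sensitivity
analysis measures. A `require_any_record` flag exists for pipelines that
prefer to drop such days.

Per-subject average daily heart rate is the unweighted mean of daily
mean HRs over valid days (day-as-unit weighting), not a pooled mean over
minutes; days with wear but different wear amounts thus count equally.
Zero valid days yield an absent estimate, never zero. Population values
are unweighted means of subject estimates over the subjects retaining at
least one valid day; subjects lost under a stricter rule are excluded
from that rule's mean but always reported in retention counts.

Monthly wear trends use consecutive 30-day blocks from each subject's
study start rather than calendar months: the supported study lengths
(90, 120 days) tile exactly and every subject's month 1 is their own
first month on device. The month-over-month change is
`(mean_{m+1} − mean_m) / mean_m`.

## Sensitivity binning and activity categories

Absolute per-subject differences in average daily step count between two
rules are binned into [0, 500), [500, 1000), [1000, 3000), [3000, 5000),
[5000, ∞) — bands aligned with the widths of the standard daily-step
physical-activity categories. Differences are binned on magnitude, not
sign; the signed convention elsewhere is `estimate(rule_b) −
estimate(rule_a)`. Activity categories follow the Tudor-Locke cutpoints
with half-open bins: [0, 5000) sedentary, [5000, 7500) low active,
[7500, 10000) somewhat active, [10000, ∞) highly active.

## Walking heart rate

A walking minute has a registered step count at or above 80 steps/min —
a cadence at which free-living minutes almost certainly belong to a
walk. The threshold comparison is inclusive by default (exactly 80
counts as walking) with a strict variant behind a switch, since a
cadence landmark and a strict "above" differ by a single step.

The minimum sample count is determined by resampling: for each n on a
grid (10 up to the total, step 10, the full total always included), the
standard error `s/√n` (sample sd, n−1 denominator) is computed on random
without-replacement subsamples and averaged over repetitions (default
100). Implementation detail: each repetition draws one uniform random
permutation and evaluates every grid n on its length-n prefix via prefix
sums — the prefix of a uniform permutation is exactly a uniform
n-subset, so each grid point's marginal distribution is the specified
one, at O(N) cost per repetition instead of O(N · grid). At n equal to
the sample total the subsample is the sample, so that grid point is
exact.

Convergence is the smallest grid n from which the mean SE stays at or
below the threshold (1 bpm default) for every larger grid n — a
sustained crossing, so a single lucky subsample cannot declare
convergence early. If the curve never settles below the threshold the
subject is "not converged". Subsampling ignores temporal order,
i.e. wear is assumed random with respect to when walking happens; the
feasibility question (how much data is needed) is insensitive to this,
but the walking-HR point estimate inherits any true wear–activity
coupling as bias. Days-to-reach is the 1-based calendar day on which the
cumulative walking-minute count first reaches the converged n.

## Group comparison

Compliance enters the tests as one number per subject: the study-average
daily wear fraction. The omnibus is the tie-corrected Kruskal–Wallis H
(chi-squared reference, k−1 df) — chosen because the wear distributions
are skewed with unequal variances and very unequal group sizes — with
the degenerate all-values-identical case defined as H = 0, p = 1. Dunn's
pairwise statistic is

`z_ij = (R̄_i − R̄_j) / sqrt( [N(N+1)/12 − Σ(t³−t)/(12(N−1))] (1/n_i + 1/n_j) )`,

with two-sided normal p-values reported both raw and Holm-adjusted; the
significance level for flagging is a parameter (default .05). The
omnibus uses scipy, the Dunn statistics are computed here directly; the
test suite checks both against independently coded textbook rank
formulas.

## Synthetic cohort generator

The generator emulates the data-generating process the analyses assume,
with ground truth retained for scoring:

* **Wear.** Each group has a daily wear target (hours). The day-d target
  is `base · (1 − decay)^(d div 30)` (geometric monthly decay —
  abandonment is roughly a steady proportional monthly decline). The
  realized day fraction is Beta-distributed around that target with
  concentration `day_concentration` (default 6 — low targets then
  produce the full 0%-to-90% day spread seen in low-compliance cohorts).
  Within a day, per-hour wear probabilities are proportional to a
  24-value diurnal profile (near-zero overnight, flat daytime) and
  water-filled so their expectation matches the day fraction, capping at
  1; a target of 24 h yields deterministic full wear. A per-subject
  `never_wear_prob` produces received-but-never-worn subjects (zero
  records).
* **Activity.** Walking bouts per day are Poisson (default 6/day), bout
  length `1 + Poisson(mean − 1)` minutes (default mean 10), per-minute
  cadence Normal(105, 10) clipped to [1, 300] steps, placed uniformly in
  an awake window (07:00–22:00); non-bout awake minutes carry Poisson
  background steps (default rate 1.5/min). Defaults give ≈ 7500
  steps/day, a realistic adult total.
* **Heart rate.** Per subject resting HR ~ Normal(65, 5) bpm; walking
  minutes add a per-bout elevation ~ Normal(40, 14) bpm (bouts differ in
  pace and context) plus minute noise of sd 10 bpm; values are rounded
  and clipped to [25, 250]. The resulting minute-level walking-HR sd of
  ≈ 17 bpm is the variability consistent with needing roughly 300
  walking minutes for a 1 bpm standard error, the regime the analyses
  operate in.
* **Coupling.** The full activity schedule is drawn first, independent
  of wear; `coupling` γ then multiplies the wear probability by (1 + γ)
  during bout minutes (capped at 1). γ = 0 is missing-at-random wear;
  γ > 0 makes worn time oversample walking. HR is present iff a minute
  is worn, and steps are registered only in worn minutes, so the
  recorded file obeys the wear-time definition by construction.
* **Truth.** Per subject: the realized mean daily step total a fully
  worn device would have registered (the pre-mask schedule), the
  walking-HR mean parameter (resting + mean elevation), the resting HR
  and the wear parameters drawn. `recovery_score` reports bias
  (estimate − truth) and RMSE per rule.
* **Determinism.** All randomness descends from one master seed:
  subject (group index, subject index) maps to
  `SeedSequence(master_seed, spawn_key=(gi, si))`, so any subject is
  regenerable in isolation and a fixed seed reproduces the minute CSV
  byte-for-byte.

The default six-group study configuration spans wear targets 20.8 →
9.8 h/day, monthly decay 8–19%, never-wear probabilities 0–7% and study
lengths 90/120 days, with 12 subjects per group — a desk-scale cohort
preserving the compliance contrasts of a multi-population wearables
study while keeping the full pipeline (including per-subject resampling)
in the tens of seconds.

What the generator does **not** model: autocorrelated HR dynamics,
heart-rate variability spectra, accelerometer waveforms, sleep stages,
device sync gaps, or mid-bout device removal (wear transitions are
clean at minute resolution). Passing tests therefore demonstrate the
pipeline's correctness and its qualitative behavior under controlled
missingness — not device-level fidelity on any particular vendor's
exports.

## Numerical choices and degenerate inputs

* Strict (`>`) thresholds everywhere a rule compares to a floor.
* Estimates are `None`/NaN when undefined (zero valid days, no HR
  minutes), never silently 0; downstream tables carry explicit
  `both_defined` / retention columns instead of dropping subjects.
* The SE grid always contains the full sample size, so convergence at
  the last point is evaluated on the exact SE.
* Duplicate subject-minutes and timestamps outside the study window are
  hard errors; files are never repaired silently.
* Variance in the prefix-sum SE computation is clamped at 0 before the
  square root to absorb floating-point cancellation on near-constant
  samples.

## Known limitations

* Wear detection trusts HR registration; algorithms fusing HR values,
  their plausible range and step counts can classify wear differently,
  and no sleep-window exclusion is applied.
* The walking-minute definition is a single cadence threshold; no bout
  segmentation or validation against labelled activity exists here.
* Months are 30-day blocks, so calendar-month seasonality is out of
  scope.
* The acceptance script's quantities are computed on the simulated
  default cohort; they characterize the method under the generator's
  assumptions, not any specific empirical dataset.
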