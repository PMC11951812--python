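# weartime

Wear-time-aware analysis of minute-level consumer-wearable (e.g. Fitbit)
data, for researchers who use these devices to monitor physical activity
in longitudinal studies.

## The problem

Consumer wearables only measure while worn, and participants wear them
less and less over a study ("wearables abandonment"). Analyses that
ignore wear time treat unworn, step-free hours as sedentary time and can
badly distort per-day estimates — yet how badly depends on the cohort's
compliance and on the estimand. This package implements the full
analysis pipeline for quantifying that effect:

* **Wear time.** The optical HR sensor registers a per-minute heart-rate
  value only while the device is on-wrist, so for any window

  `wear time = (# minutes with registered heart rate) / (total minutes)`,

  with 1440 total minutes in a 24-hour day.
* **Valid-day rules.** A day is retained for analysis under a named rule:
  `none` (every day valid), `stepcount1000` (daily steps > 1000), or
  `weartime80` (daily wear time > 80%, i.e. > 19.2 h); custom step/wear
  floors are supported. Per-subject estimates — average daily step count
  and average daily heart rate — are means over a rule's valid days.
* **Sensitivity analysis.** Population tables per (group, rule),
  per-subject estimate differences between rules, binning of absolute
  step differences (0–500, 500–1000, 1000–3000, 3000–5000, 5000+), and a
  report of subjects whose Tudor-Locke activity category (sedentary /
  low / somewhat / highly active) flips between rules.
* **Walking heart rate.** Minutes with cadence ≥ 80 steps/min are treated
  as walking; the HR values in those minutes are the walking-HR sample.
  The minimum sample size is found empirically: the mean standard error
  `SE = s / √n` over random subsamples of increasing n, converged once it
  stays ≤ 1 bpm. Each subject is then labelled by which questions their
  data can answer: `both`, `steps_only`, `walking_only`, or `neither`.
* **Group comparison.** Kruskal–Wallis omnibus on per-subject mean daily
  wear time with Dunn pairwise z tests (tie-corrected, Holm-adjusted).
* **Synthetic cohorts.** A generator producing minute-level cohorts with
  a diurnal wear profile, day-to-day variability, geometric monthly
  wear decay, never-worn subjects, Poisson walking bouts with ~105
  steps/min cadence, an HR model (resting baseline + per-bout walking
  elevation + minute noise), optional wear–activity coupling, and a
  ground-truth table for scoring estimator bias.

## Worked example

```python
import numpy as np
from weartime import (default_study_configs, generate_cohort, cohort_summaries,
                      population_estimates, PRESET_RULES, classify_feasibility)

configs = {k: v for k, v in default_study_configs(n_subjects=6).items()
           if k in ("hct_caregivers", "onc_patients")}
cohort, truth = generate_cohort(configs, master_seed=7)
summaries = cohort_summaries(cohort)

pop = population_estimates(cohort, (PRESET_RULES["none"], PRESET_RULES["weartime80"]),
                           summaries=summaries)
print(pop.to_string(index=False, float_format=lambda x: f"{x:0.1f}"))
```

```
         group       rule  n_subjects  n_retained  mean_n_valid_days  mean_avg_daily_steps  mean_avg_daily_hr
hct_caregivers       none           6           6               90.0                6898.1               69.3
  onc_patients       none           6           6              120.0                3261.3               68.7
hct_caregivers weartime80           6           6               52.7                7316.9               69.2
  onc_patients weartime80           6           5                1.5                7501.2               66.9
```

The high-compliance caregiver group (~19.3 h/day of wear here) barely
moves between rules (~420 steps), while the low-compliance patient group
(~7.6 h/day) jumps by over 4000 steps/day: under `none`, its unworn hours
are silently counted as step-free. Average daily heart rate moves by
under 2 bpm in both groups — it is robust to wear time.

The same low-compliance subject can still support the walking-HR
question:

```python
lab = classify_feasibility(cohort["onc_patients_002"], seed=1)
print(f"{lab.subject_id}: {lab.label}, n_required={lab.n_required}, "
      f"days_to_reach={lab.days_to_reach}, walking_hr={lab.walking_hr_mean:.1f}")
```

```
onc_patients_002: walking_only, n_required=310, days_to_reach=15, walking_hr=113.9
```

No day exceeds 80% wear (no daily-step estimate), but ~310 walking
minutes — reached by study day 15 — pin the walking heart rate to a
standard error below 1 bpm.

## Command line

```bash
weartime simulate --seed 7 --out run/            # minute.csv + truth.csv + manifest
weartime summarize --input run/minute.csv --out run/days.csv
weartime sensitivity --input run/minute.csv --rules none,weartime80 --out run/
weartime walking-hr --input run/minute.csv --seed 7 --out run/walking.csv
weartime compare --input run/minute.csv --out run/
weartime all --seed 7 --out run/                 # the whole pipeline
```

Every stochastic stage takes a `--seed` and records it, with output
checksums, in `manifest.txt`; re-running with the same seed reproduces
outputs byte-for-byte.

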