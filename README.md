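# damkit

Behavioral-aging analysis for *Drosophila* activity-monitor (DAM) data:
from per-minute infrared beam-break counts to sleep, circadian profiles,
PCA aging scores, and lifespan statistics.

Laboratories that record fly locomotion with beam-break monitors routinely
ask the same questions: how much does each fly sleep, what does its 24 h
activity pattern look like, how do those change with age or under adverse
conditions (high temperature, caffeinated or high-carbohydrate food,
constant darkness), and how do genotypes differ in lifespan?  `damkit`
implements that pipeline as a tested library plus a small CLI:

* **I/O** — a documented tab-separated monitor dialect (one row per minute,
  32 channels) with explicit missing-minute handling, plus cohort metadata
  tables (`read_monitor`, `write_cohort`, ...).
* **Sleep** — the standard immobility criterion: any run of ≥5 consecutive
  zero-count minutes is a sleep bout (`call_sleep`, `sleep_summary`), with
  dead-fly exclusion (`filter_dead`).
* **Profiles** — 48-bin 24 h profiles (30-min bins, bin 0 at lights-on
  7:00), per-fly daily averages and group means ± SE (`daily_profile`,
  `group_profile`, `daily_means`).
* **Aging score** — PCA over pooled per-fly profiles.  After an explicit
  sign-fixing rule, PC1 scores the overall level (positive = active,
  short-sleeping, "young-age") and PC2 the daily pattern (positive =
  unimodal daytime-shifted, "old-age"); flies are classified by score sign
  (≤0 vs >0), class rates are tabulated per strain × age group, and rates
  are compared with a 2×2 Pearson chi-square test (`fit_pca`, `orient`,
  `score_table`, `rate_table`, `compare_rates`).
* **Survival** — Kaplan–Meier curves S(t) = Π(1 − dᵢ/nᵢ), log-rank
  (Mantel–Cox) tests, and dose–response summaries with median lifespans
  (`km_estimate`, `logrank_test`, `dose_response_summary`).
* **Synthetic cohorts** — a generative model (two-state Markov chain with
  circadian Poisson rates, Gompertz mortality) with slow- and fast-aging
  strain presets, so every stage is testable without hardware
  (`simulate_cohort`, `simulate_lifespans`).  See `docs/methods.md`.

## Worked example

```python
import damkit as dk

# simulate a small aging study: two strains at 4 ages, 50 flies each,
# constant darkness, 29 C
cfg = dk.SimConfig(n_days=4, light_regime="DD", temperature_c=29.0, seed=0)
groups = [(p, dk.AgeMorph.for_age(a, p.aging_rate), 50)
          for p in (dk.CANTON_S, dk.HARWICH) for a in (3, 7, 18, 32)]
traces = dk.simulate_cohort(groups, cfg)

# sleep and profiles
sleeps = [dk.call_sleep(t) for t in traces]          # 5-min immobility rule
profiles = [dk.daily_profile(t) for t in traces]     # 48-bin 24 h profiles

# PCA aging score
model = dk.orient(dk.fit_pca(profiles))
print(f"PC1/PC2 explain {100*model.explained_fraction[0]:.1f}% / "
      f"{100*model.explained_fraction[1]:.1f}% of variance")
scores = dk.score_table(model, profiles)
joint = dk.joint_rate_table(scores).set_index(["strain", "age_days"])
print(joint["rate_le0_gt0"].unstack().round(2))
```

Output:

```
PC1/PC2 explain 52.5% / 25.5% of variance
age_days   3     7     18    32
strain
canton_s  0.0  0.00  0.02  0.20
harwich   0.0  0.12  0.70  0.82
```

The joint old-age rate (PC1 ≤ 0 *and* PC2 > 0: low overall activity with a
unimodal daytime-shifted pattern) rises with age in both strains and is
higher at every age in the fast-aging strain — the planted aging structure,
recovered by the scoring.  Lifespans behave accordingly:

```python
import pandas as pd
slow = dk.simulate_lifespans(dk.CANTON_S, 300, seed=1, group="slow")
fast = dk.simulate_lifespans(dk.HARWICH, 300, seed=2, group="fast")
print(dk.km_estimate(slow).median, dk.km_estimate(fast).median)
res = dk.logrank_test(pd.concat([slow, fast]))
print(f"log-rank chi2={res.statistic:.1f}, p={res.p_value:.2g}")
```

```
42.0 28.0
log-rank chi2=189.0, p=5.2e-43
```

## Command line

```bash
damkit simulate --out cohort/ --seed 7 --n 16 --days 5    # monitor files + metadata.csv
damkit score --profiles profiles.csv --out scored/        # model.json, scores.csv, rates
damkit survival --events deaths.csv --by dose --out surv/ # KM curves, log-rank tests
```

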