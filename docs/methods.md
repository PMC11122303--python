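# Methods

## Scope

`damkit` analyzes per-minute beam-break counts from Drosophila activity
monitors (DAM): it calls sleep by the immobility criterion, reduces traces to
48-bin 24 h profiles, scores behavioral aging with a two-component PCA and
sign classification, compares class rates with a chi-square test, and
compares lifespan cohorts with Kaplan–Meier curves and the log-rank
(Mantel–Cox) test.  A synthetic cohort generator produces data with the
strain / age / condition structure these analyses assume, so the whole
pipeline is testable end to end without monitor hardware.

## Sleep calling

Sleep is defined operationally as any run of at least `threshold_min`
(default 5) consecutive minutes with zero beam breaks; each maximal such run
is one bout.  Choices at the edges:

* Minutes without a valid reading are MISSING and break runs; only the
  observed part of a run is scored.  Zero-filling missing minutes would
  fabricate sleep, so it is never done.
* Runs truncated by the start or end of the recording count as sleep if the
  observed portion reaches the threshold (conservative: no unobserved
  immobility is assumed).
* Runs crossing midnight are a single bout; the criterion is purely
  run-length based.

Dead flies are excluded before averaging: a fly with no observed activity in
its final 24 h (configurable) of recording is removed and reported with its
time of last movement.  Terminal immobility would otherwise enter the
averages as one enormous sleep bout.

## Profiles

One-minute data are averaged over 30-min intervals, giving 48 values per
24 h.  Activity bins are mean counts/min over the *observed* minutes of the
bin, so partially observed bins stay comparable; sleep bins are sleep minutes
rescaled to a 30-observed-minute basis (hence in [0, 30]).  A bin with more
than 50% of its minutes missing is itself missing (NaN).  Bin 0 is anchored
at lights-on, 7:00 (Zeitgeber time 0) by default — bins 0–23 are the
photophase under the standard 12:12 light-dark schedule — and the anchor is
configurable.  Daily profiles average complete recording days per clock bin;
the first day is discarded by default as acclimation.  Conservation laws
(30 × bin sum = total counts; sleep bins sum to daily sleep minutes) hold
exactly on fully observed days and are enforced by tests.

## Aging score

Per-fly 48-bin profiles are pooled and decomposed by PCA on the covariance
matrix of the raw binned values (bins share units, so no correlation
scaling).  Activity and sleep ensembles are fitted separately.  The two
leading components are reported with their explained-variance fractions.

Eigenvector signs are arbitrary, so an explicit orientation rule makes the
scores read as aging phenotypes:

* **PC1 (level).**  Sign fixed by the dot product of the loading vector with
  the all-ones vector: positive score ⇒ above-average overall activity
  (activity profiles) or below-average overall sleep (sleep profiles).  Both
  are the "young-age" direction.
* **PC2 (pattern).**  Sign fixed by a daytime contrast vector (+1 on bins
  covering 10:00–16:00, −1 on bins covering 19:00–22:00): positive score ⇒
  the unimodal daytime-shifted "old-age" pattern.  For activity profiles the
  old pattern has its activity mass in the daytime window (contrast dot
  product positive); for sleep profiles the old pattern has its *wake*
  window — a sleep trough — in daytime, so the same semantic direction
  corresponds to a negative contrast, and the sign rule is kind-aware.  The
  applied rule is recorded in the model.

Flies are classified per component by score sign; a score of exactly 0 falls
in the ≤0 class.  Rates are tabulated per group (strain × age class) both
per component and jointly over the four (PC1, PC2) sign categories; the
joint "old-age" cell (PC1 ≤ 0 and PC2 > 0: low level *and* daytime-shifted
pattern) is the single most specific old-phenotype readout and is what the
end-to-end recovery test asserts on.  Two groups' rates are compared by a
Pearson chi-square test on the 2×2 counts, without continuity correction by
default (Yates correction available), with a warning when an expected cell
is below 5; a Holm adjustment helper covers families of comparisons.  No
multiple-testing adjustment is applied by default.

## Survival

Lifespan cohorts are plain tables (fly, group, day, death/censor flag).
Kaplan–Meier estimation and the log-rank test are computed with lifelines;
the module fixes the conventions: censored flies leave the risk set after
their censoring time, tied death days share one pooled risk set, flies alive
at study end are right-censored, and the median is the smallest time with
S(t) ≤ 0.5.  The dose–response summary reports per-dose medians and pairwise
log-rank tests against the ×0 control, optionally Holm-adjusted.

## Synthetic cohorts

The generator is a two-state (active/quiescent) Markov chain per fly on
1-minute steps.  Active minutes draw Poisson counts from a time-of-day rate

    λ(t) = mesor + morning bump + evening bump + daytime bump,

Gaussian bumps on the circular 24 h axis (defaults: morning 8:00, evening
19:00, width 1.5 h).  Quiescent minutes are exactly zero.  The
quiescence-entry probability is gated in anti-phase to λ(t)
(`sleep_circadian_coupling`, default 0.75), producing a daytime siesta,
consolidated night sleep, and wake concentrated at the activity peaks; the
exit probability is 1/`mean_bout_min`.  With the default young parameters a
fly produces ≈1.3–1.7 counts/min and ≈400–460 min sleep/day in ≈11–13
bouts — within the range commonly reported for young male flies.

**Aging** is a smooth morph with a common log-age progression
x = min(1, rate·ln(1 + age/5 d)/ln(8)), i.e. fastest early in life, with
`aging_rate` the fraction of the full morph reached at 35 d.  At full morph:
the background level (mesor, morning and evening amplitudes) loses 50%;
peaks drift 1.5 h earlier; sleep pressure gains +0.012/min; and amplitude is
handed over from the evening peak to an emerging daytime peak at a fixed
clock position (14:00, widened 30%) — the bimodal evening-dominant rhythm
becomes unimodal and daytime-shifted.  The handover form (two fixed bump
positions exchanging amplitude, rather than one peak migrating continuously)
was a deliberate choice: a migrating peak sweeps a curved one-parameter
family through profile space, and PCA represents the extremes of such a
family with a quadratic ("arch") component, which breaks the monotone
reading of the pattern score for the most aged groups.  An amplitude
handover keeps the ensemble in a low-dimensional linear subspace where the
two-component score is faithful.

**Strains.**  Two presets share the young-adult baseline except for the
mesor (slow ager 1.15, fast ager 1.0 counts/min) and differ in `aging_rate`
(0.5 vs 1.05) and Gompertz mortality (a = 0.002/d, b = 0.08/d vs a = 0.004/d,
b = 0.10/d; medians ≈ 44 vs ≈ 30 d).  The behavioral strain contrasts the
assay observes — lower activity, more sleep, earlier unimodal patterns, at
every tested age — thus emerge mostly from the different aging rates, with
the mesor offset providing a baseline level difference that is nearly
invisible to the (approximately zero-sum) pattern component.

**Inter-fly variance** is not characterized by published monitor data, so it
is exposed as parameters rather than asserted: a lognormal multiplier on
each fly's overall rate (CV 0.40 in the presets), a lognormal multiplier on
sleep pressure (CV 0.25), and Gaussian jitter of the peak times (SD 0.35 h).
The level CV is deliberately the dominant variance source: it makes the
first principal component the overall-level axis and leaves the
evening-to-daytime handover to the second, mirroring the level-first,
pattern-second component structure the scoring method assumes.

**Conditions** enter as direction-of-effect modifiers: caffeine doses reduce
activity (×0.9/×0.8/×0.6 for ×1/×2.5/×10), add sleep pressure, and scale the
mortality hazard (×1.2/×1.4/×2.0); a high-carbohydrate diet reduces activity
and adds sleep pressure; temperature scales activity by 2%/°C from 25 °C;
constant darkness damps the light-masked morning peak by ×0.4.

**Lifespans** are drawn from the Gompertz law (hazard a·e^{bt}) by inverse
CDF, rounded up to whole days by default (death counts happen at food
changes, not continuously; a `round_to_days=False` switch gives continuous
times), and right-censored at `max_day`.

**Determinism.**  Per-fly seeds are spawned from the master seed; identical
inputs give bit-identical traces.

## What the simulations do and do not show

Passing tests demonstrate that the pipeline recovers the structure the
generator plants: the sleep rule matches an independent scan, profiles
conserve counts, the PCA recovers planted orthonormal directions to 1e-6,
the oriented score classification recovers monotone, strain-ordered old-age
rates from a 4-age × 2-strain design (n = 50/group), survival estimates
match hand product-limit calculations, the log-rank p agrees with a
100 000-shuffle permutation null, and its null rejection rate is nominal.
They do not show that real monitor data satisfy the generator's assumptions:
real flies have non-Poisson overdispersion within the active state,
activity- and age-dependent bout-length distributions, inter-individual
aging-speed variation, and monitor artifacts (dead channels, double counts)
beyond the missing-minute model.  Explained-variance fractions on synthetic
ensembles (≈50/25% activity, ≈23/6% sleep at the default design) depend on
the planted variance structure and are not estimates of any published value.

## Numerical and statistical choices

* PCA uses a full SVD (deterministic); models need ≥3 profiles and non-zero
  total variance; missing bins must be resolved (error, or per-bin mean
  imputation on request).
* Orientation raises an error when a fixing contrast is exactly zero instead
  of guessing.
* The chi-square test is the asymptotic Pearson statistic; at n = 40 its
  p-value differs from the exact conditional one by O(1/√n), which is why
  the permutation cross-check in the tests runs at n = 200.  The statistic
  itself matches the 2×2 closed form to 1e-9 on an exhaustive sweep of all
  tables with n ≤ 40.
* The log-rank permutation check uses continuous lifespans to avoid heavy
  day-rounding ties; the test statistic matches an independent risk-set
  implementation to 1e-6.
* Type-I error and power checks use 2000 and 300 replicates respectively —
  sizes chosen to keep the default suite under a minute of survival testing
  while leaving Monte-Carlo error well below the asserted margins.
* End-to-end recovery simulates 4 recording days per fly (first discarded as
  acclimation); 50 flies per group, 8 groups.

## Known limitations

* The generator's condition effects are directional only; it is not fitted
  to any real dataset and should not be used to power real experiments.
* `write_monitor` requires co-housed traces to share a missing-minute
  pattern (monitors fail per row); per-channel dropout is not modeled.
* Only two-group log-rank comparisons are provided (pairwise vs control for
  dose designs); no trend test, no Cox regression, no frailty.
* The PCA scoring assumes a shared bin anchor and complete profiles; flies
  that die mid-study contribute only their pre-death days if they pass the
  dead-fly filter.
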