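# Methods

`actisleep` reimplements an actigraphy phenotyping and case-control
analysis pipeline for multi-day wrist-accelerometer studies: epoch-level
activity and light series are reduced to daily sleep, circadian and
physical-activity traits, aggregated to per-person features, screened for
case association with a cross-validated elastic net, and modelled at the
day level with mixed-effects interaction regressions. Because raw cohort
data of this kind are rarely shareable, the package ships a synthetic
cohort generator with known ground truth; every stage is tested against
it.

## The synthetic cohort generator

### Epoch tier

Each participant contributes `n_days` (default 21) of 60-s epochs
starting at noon of a start date drawn across the year (so seasonal scans
have support). The waking activity profile is a two-harmonic cosinor

    a(t) = M + A1 cos(2*pi*(t - phi1)/24) + A2 cos(4*pi*(t - phi2)/24)

with defaults M = 85, A1 = 50, A2 = 12 mg, peak at 15:00. These values
are artifact choices: the protocol emulated here does not publish its
cohort's activity distribution. They were picked once so that, under the
conventional mg cutoffs (inactive < 40, light 40-100, moderate 100-400,
vigorous >= 400), the waking baseline sits clearly above the inactive
cutoff — sedentary time is then driven by deliberately imposed sedentary
minutes, not by noise straddling a threshold. On top of the profile:

* **Sedentary imposition.** Per day, a target sedentary duration
  (group-specific mean: controls 6 h, cases 7 h, SD 1.5 h, individual
  jitter 0.75 h) is realized by overwriting that many randomly chosen
  afternoon/evening minutes with 1-30 mg values. Imposition happens
  *after* activity pulses so that the recorded sedentary truth is exact.
* **Activity pulses.** Poisson(3)/day moderate-to-vigorous bursts
  (5-25 min, +120-500 mg) during the afternoon.
* **Sleep.** One nightly window per noon-to-noon day: onset ~ N(23.5,
  0.5 h) (clipped so the window stays inside the day), duration ~ N(8,
  0.5 h). Inside the window activity is multiplied by 0.02 — suppressed,
  never zeroed, so sleep cannot alias with exact-zero non-wear.
  Awakenings (WASO) are Poisson(2)/night, exponential lengths (mean
  8 min, clipped 1-30), boosted by +30 mg (awakenings carry movement),
  and placed at least 20 min interior to the window: wake abutting the
  window edge is onset latency or terminal wake by definition, and
  leaving it in would make the "true WASO" label ambiguous for any
  scorer based on sustained-low-activity runs.
* **Sleep-sedentary coupling.** The night's duration is shifted by
  `slope_group x (sedentary - group mean)` minutes per hour (defaults
  -23.5 for cases, -17.1 for controls), plus individual (SD 20 min),
  family (SD 10 min) and nightly residual (SD 40 min) Gaussian terms.
* **Group contrasts.** Cases get a 0.9 multiplier on waking activity
  (more sedentary/less light activity), 2x onset-timing SD and 1.6x
  duration SD (lower sleep regularity, higher duration variability),
  and +1 h mean sedentary time.
* **Non-wear.** Poisson(`nonwear_rate`) exact-zero runs of
  `nonwear_len` minutes placed outside sleep, recorded in the truth.
* **Light.** A squared-cosine daylight curve peaking at 13:00 (400 lux),
  floored at 30 lux while awake, 0.5 lux during sleep, log-normal noise.

Epoch noise is Gaussian (SD 8 mg) added before the sleep suppression and
clipped at zero. All randomness flows from one seeded generator with one
spawned child stream per participant, so cohorts are bytewise
reproducible and participant-order independent.

### Day tier

Mixed-model recovery tests should not be confounded by feature-extraction
error, so a second generator emits day-level rows directly from the
variance-components model the association stage fits:

    TST_ij = intercept + slope_g(i) * sed_ij + u_i + v_f(i) + e_ij

with intercept = `sleep_dur_mu` x 60 min. Families are assigned from a
size distribution (1-3 members); participants nest within families.

### Diary

Nightly diary reports equal the true onset/offset/total-sleep/efficiency
plus a configured additive bias and Gaussian reporting noise. Defaults:
onset reported 15 min early, efficiency overestimated by +12 percentage
points. Efficiency is deliberately *not* clipped at 100: clipping would
censor the additive bias on near-perfect nights and hide it from the
Bland-Altman recovery checks. Real diaries saturate at 100; treat the
unclipped scale as a generator simplification.

### What the generator does not emulate

No raw 30 Hz tri-axial signal, device calibration error, temperature
channel, naps, shift work, weekday/weekend structure in behaviour, or
non-Gaussian heavy-tailed activity. Passing tests therefore demonstrate
algorithmic correctness and statistical calibration on this idealized
process, not performance on real recordings.

## Preprocessing and QC

Non-wear is any maximal run of exactly-zero activity strictly longer
than 100 min (zero after rounding to 3 decimals, so float dust cannot
split runs); runs overlapping the cosinor-predicted rest span are exempt
when such spans are supplied, since long stillness is expected there.
Days are noon-to-noon half-open windows numbered from 1, so each night
lies within one day; weekend status is the civil Saturday/Sunday of the
window start. A day is valid with >= 20 h of wear; a participant is
excluded with fewer than 5 valid days or mean nightly sleep <= 3 h. The
"<20 h" rule is read as a per-day validity criterion feeding the 5-day
rule (the protocol wording is ambiguous between day- and
participant-level; `apply_qc` exposes the thresholds). Note the QC
monotonicity caveat: adding a valid day can only help the day count, but
a valid day with very low sleep can still drag the mean under the sleep
rule; the property holds whenever the added day's sleep exceeds 3 h.
Odd/even partitioning is by day-index parity, with a Fisher exact test
of weekend balance between the halves.

## Sleep and circadian features

The two-harmonic cosinor is fitted by linear least squares on
(cos, sin) regressors over wear-valid epochs — exact on noiseless input.
Amplitude/phase come from the rectangular coefficients; the fitted
minimum, maximum and range are evaluated on a 1-s grid; alpha (hours
above mesor) uses 1-min midpoint bins so a symmetric sinusoid scores
exactly 12 h. Daily fits need >= 12 h of valid data, whole-recording
fits >= 24 h.

Sleep detection: the candidate rest span is the longest below-mesor
stretch of the day's fitted curve; onset is the start of the first run
of >= 10 consecutive minutes with activity below `theta_sleep` (default
10% of the recording mesor), offset the end of the last such run.
Qualifying runs may extend past the candidate's edges — the fitted curve
often crosses its mesor before final waking, and clamping at the
crossing truncates long nights. Within the window, awake epochs
(activity >= theta) form awakenings (runs >= 1 min; separately counted
at >= 5 min); WASO is total awake time; efficiency is
100 x sleep/period. Total sleep time counts in-window sleep only (nap
detection off by default). The scotoperiod is light < 10 lux.

SRI is computed on the unclipped -100..100 scale,
`200 x P(same state at the same clock time on consecutive days) - 100`,
pairing only consecutive days (gaps break pairing). Reports annotate
negative values as below-random rather than clipping, which would
destroy the null test.

`day_duration` (onset-to-next-onset) is an interpretation: the trait
catalogue names a "duration of the day" without defining it. The core
sleep-trait list is the ten named traits plus this one.

## Activity features

Bouts implement the 80% rule: from an at-level epoch, the minimum-length
window qualifies if its at-level fraction is >= 0.8; it is then extended
while the fraction holds and trimmed to end on an at-level epoch, never
below the minimum window. The published definition fixes only the 80%
criterion, not the windowing; the greedy left-anchored scheme here is
the main divergence risk against other implementations (GGIR's internal
windowing differs in unpublished details). Blocks are maximal
constant-level runs; "unbouted" time at a level is at-level time outside
that level's bouts. M10/M5/L10/L5 windows are exhaustive 1-epoch-step
searches within the day (ties to earliest onset); light statistics are
taken over the activity-defined M windows. "Mixed activity" (5-min
majority windows containing both light and moderate) and
"sitting/standing" (inactive but nonzero activity) are explicit
surrogate definitions for classifier-derived classes that are out of
scope. Sedentary time excludes the sleep period (falling back, flagged,
to the whole day when no window was found).

## Aggregation and standardization

Per-person features are the within-individual mean, median and SD of
each day-level trait, computed separately on odd days, even days or all
days. Clock-time traits use circular statistics (resultant-vector mean,
circular SD, minimal-arc median): linear averaging of onsets around
midnight is simply wrong. Z-scoring uses the whole assembled sample
(cases and relatives pooled) with population (ddof=0) SD; columns
constant in either parity table are dropped from both so the odd and
even tables always share one column set.

## Elastic-net selection

The classifier is penalized logistic regression (scikit-learn saga)
with mixing parameter alpha on a 0-1 grid (default step 0.05) and an
inverse-strength path C. Median imputation and standardization are
learned on the training table and frozen for any evaluation table.
Alpha tuning runs `n_iterations` (default 1000; reduce for exploratory
runs) random re-partitions of participants into `n_folds` (default 10)
folds per alpha — the protocol text does not say what varies across
iterations, and re-randomized fold assignments are the natural reading —
scoring each iteration's pooled out-of-fold AUC at the
deviance-minimizing penalty; the best alpha maximizes the median AUC,
ties to the smaller alpha. Folds always partition participants, never
days, and an optional 15% participant-level holdout is carved off before
any tuning.

Two penalty-strength rules are available: `min` (deviance-minimizing,
the default) and `1se` (strongest penalty within one SE of the minimum).
CV-min elastic nets over-select by construction — at n = 300 with 8 true
and 100 null features the min rule keeps all 8 true features but admits
a median of roughly 35 nulls, while the 1se rule keeps 8/8 with roughly
9 — so use `1se` when false-positive control matters more than
completeness.

Unpenalized covariates (age, sex) enter through a column-scaling trick
(x100 before fitting, coefficients rescaled), making their effective
penalty negligible without a custom solver. AUC confidence intervals use
the asymptotic placement-value (DeLong-style) variance. Selected
features are reduced by complete-linkage clustering of 1 - |r| with the
tree cut at 0.5; each cluster's lead is its largest-|coefficient|
member, ties to column order.

## Association models

The day-level model regresses a nightly sleep trait on a daytime
activity exposure with age, age², sex and group as fixed effects and two
variance components: a family random intercept and an individual
intercept nested inside family (statsmodels MixedLM; nesting matches
family-study structure — the source wording does not state crossing).
Estimates come from REML; likelihood-ratio tests refit by ML. Main
effects are tested in the model without the interaction; the interaction
by comparing the with/without-interaction ML fits. The identity
`case slope = control slope + interaction coefficient` is exact by
construction. Deterministic inputs (residual variance ~0) fall back to
an exact OLS fit flagged `singular`; near-zero estimated variance
components are also flagged rather than silently accepted. Both adjusted
(age/age²/sex) and unadjusted models are available, since covariate
adjustment visibly shifts the coupling slopes.

Supporting procedures: Benjamini-Hochberg step-up FDR (statsmodels);
stepwise-AIC linear regression (bidirectional by default — the source
describes the procedure both as forward and as bidirectional; both are
supported), with perfectly collinear candidates dropped pre-search;
a seasonal-confounding scan (meteorological northern-hemisphere
quarters, per-trait mixed model with participant intercepts, ML LRT
omnibus, BH across traits, Wald pairwise contrasts BH-corrected within
trait); covariate-adjusted multi-group contrasts with BH across
features (rank-sum variant available); and Spearman matrices with
pairwise-complete handling.

Questionnaire scores are age-adjusted by residualizing on a linear age
term before the stepwise search (the adjustment is not defined at the
source; residualization is the conventional choice).

## Agreement

Bland-Altman differences are oriented diary minus derived, so positive
bias means diary over-reporting; limits of agreement are
bias ± 1.96 x SD of differences. Clock-time traits are differenced on
the circle (wrap to ±12 h) first.

## Numerical choices and problem sizes

* Zero means exactly 0.0 after rounding activity to 3 decimals.
* Window/bout boundaries are half-open; intensity boundaries belong to
  the upper class.
* Cosinor extrema on a 1-s grid; alpha on 1-min midpoint bins.
* The saga path scan uses tol 1e-3 (only the deviance curve matters
  there); final fits use tol 1e-4.
* Test and demo problem sizes are scaled to what the checks need:
  slope-recovery cohorts use 300 participants x 18 days; null-LRT
  calibration uses 300 cohorts of 30 participants x 6 days; the demo
  pipeline uses 60 participants x 21 days with a reduced tuning grid.
  `SelectionConfig` defaults keep the full protocol (alpha step 0.05,
  1000 iterations, 10 folds).

## Known limitations

* Sleep detection assumes a monophasic nightly pattern inside a
  noon-to-noon day; shift work and split sleep will misdetect.
* The bout windowing is one defensible reading of the 80% rule; other
  implementations bin and extend differently. Like any left-to-right
  greedy scheme it is not monotone under label promotion in general: an
  epoch promoted to at-level ahead of an existing bout can create an
  earlier qualifying window that preempts a better later one. Promotion
  after the last bout is monotone (verified exhaustively on short
  sequences).
* The elastic net's unpenalized-covariate scaling trick is approximate
  (penalty reduced ~1e4-fold, not exactly zero).
* MixedLM occasionally warns about boundary convergence on degenerate
  variance structures; such fits are flagged, not suppressed.
* The generator's group effects are stylized; effect sizes were chosen
  for testability, not to match any cohort's empirical distributions.
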