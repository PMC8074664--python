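# Methods

## The analysis

`hearbeat` links two asynchronous log streams from a cohort of
hearing-aid users: 60-s ambient-acoustics logs (SPL, SML, SNR in dB and
a four-class soundscape) and ~7.6-min heart-rate logs (5-min running
means, bpm).  The analysis proceeds in four stages.

**Acoustic estimators.**  The in-device estimators are emulated from an
instantaneous broadband level series in dB: a one-pole low-pass IIR
smoother with a 63 ms time constant produces the SPL; asymmetric one-pole
followers produce a top (peak) and bottom (valley) tracker — the bottom
tracker recovers upward slowly (default 3 s, from the plausible 1–5 s
range) and drops quickly (30 ms), the top tracker mirrored; SML is top
minus bottom and SNR is SPL minus bottom.  All processing stays in the
dB domain, because every derived quantity is a difference of level
trackers.  Frames are 1-s summaries of the per-sample estimators; a
threshold decision list over (SPL, SNR, SML) classifies each frame
(Quiet if SPL < 52 dB; Speech if SNR ≥ 8 dB and SML ≥ 15 dB; then
Speech-in-Noise at SNR ≥ 4 dB and SML ≥ 10 dB; else Noise).  The real
classifier is proprietary, so these rules are a documented stand-in, and
the thresholds are configuration, not fixed truths.  Sixty frames
aggregate to one log (arithmetic dB means; modal class, ties to the more
complex class, ordered Quiet < Speech < Speech-in-Noise < Noise).

**Preprocessing.**  Only logs between 06:00 and 24:00 count as valid
(device likely unworn at night).  Each HR log at time *t* is joined with
the arithmetic dB means and modal class of the sound logs in the
half-open window (*t* − 300 s, *t*]; the window is half-open so a log on
the boundary of two adjacent windows is counted once.  At least 3 of the
5 expected sound logs are required (≥ 60% window coverage; the minimum
is configurable because the original procedure leaves it unstated).
Records below the pooled 5th or above the pooled 95th HR percentile
(linear-interpolation quantiles) are dropped, then participants with
fewer than 50 records.  The stage order — daytime, alignment, percentile,
participant — is fixed and every stage reports in/out/dropped counts.
GPS fixes are turned into per-minute speeds via the haversine
great-circle distance (r = 6 371 000 m), averaged over the same windows;
a record is excluded only if its *window-mean* speed exceeds 10 m/s, and
deciles of the pooled retained speeds (ties to the lower bin) feed the
movement-adjusted models.

**Mixed models.**  Heart rate (or log heart rate) is modelled with fixed
effects on either the standardized window acoustics, the soundscape
class (Quiet reference), their interaction (with Speech-in-Noise and
Noise collapsed to "Noisy", whose acoustics overlap), or window-mean
movement; random structure: participant intercept, a participant slope
per continuous predictor, and weekday and hour intercepts nested within
participants (movement-decile level available); residual AR(1) across
consecutive records within a participant-day, on record order — unequal
gaps are deliberately ignored, mirroring the discrete-lag autoregressive
convention of classical mixed-model software.  Random levels are
mutually independent with diagonal covariance; the covariance between
intercepts and slopes is not identifiable at this scale and is omitted.

Estimation maximizes the exact marginal likelihood (ML default so that
likelihood-ratio tests against intercept-only models are valid; REML by
flag).  Because all levels nest in participants, the covariance is block
diagonal; each block is handled by whitening with the AR(1) innovations
operator (O(n)) and the Woodbury identity on the Gram matrix of
[response, fixed design, scaled random columns].  β and σ² are profiled;
the optimizer works on log variance ratios and arctanh φ from the
deterministic start (every level at 10% of the response variance,
φ = 0), with two perturbed restarts on failure; convergence tolerance
1e−12 on the objective.  Wald 95% CIs are β ± 1.96 se.  The likelihood
is validated against a dense multivariate-normal oracle (≤ 1e−8), against
statsmodels MixedLM at φ = 0, and against R's nlme (`lme` + `corAR1`)
on a random-intercept AR(1) model.

**Effect sizes and contrasts.**  The GVIF uses the Fox–Monette
determinant ratio on the correlation matrix of the non-intercept
columns.  The partial variance explained compares level-wise residual
sums-of-squares (observation-level residuals after removing predicted
random effects; sums of squared weekday- and hour-level predictions)
between the full model and an intercept-only null.  The null keeps the
*identical random-effect law*: same structure and the variance
parameters held at the full model's estimates, with only the intercept
and residual scale re-profiled.  Re-estimating the null's variances
freely would let the mean-zero random slopes absorb a shared fixed
effect almost entirely and understate the fixed-effect contribution.
`RF2` replaces the null denominator with the total sum-of-squares.
Interaction contrasts versus the Quiet slope are the interaction
coefficients themselves (Quiet is the reference), with Wald tests.
Log-scale coefficients back-transform to percent HR change per dB via
(exp β − 1)·100.

**Descriptives.**  Per-class CDFs (percentiles 1–99 per participant;
across-participant median with a bootstrap-over-participants 95% CI),
hourly quartiles and occupancy (occupancy rows sum to 100%), and
marginal-mean decile regressions: HR and each acoustic variable z-scored
per participant (removing device and baseline offsets), optionally
stratified at 60 dB window SPL (the printed overall median, kept as a
constant; a flag re-estimates it), pooled, decile-binned (pooled edges,
ties down), and the 10 bin means regressed on mid-decile bin centers
with an F(1, 8) test.  Equivalent-continuous-level (Leq) aggregation is
offered alongside arithmetic dB means, since both conventions appear in
this literature.  The soundscape comparison is a one-way
repeated-measures ANOVA on participant-by-class mean HR with
Greenhouse–Geisser correction (Huynh–Feldt by flag) and Bonferroni
paired post hocs; the epsilon machinery comes from pingouin, and the
F statistic is cross-checked against the textbook two-way decomposition
in the tests.

## The synthetic cohort generator

The generator is the package's ground-truth instrument: it emulates the
statistical structure the analysis assumes, with every sampled quantity
recorded so that fits can be scored against the truth.

Per participant (all randomness from one cohort seed split per
participant with stable `SeedSequence` spawn keys, so output is
independent of iteration order):

* **Wear process** — per-minute two-state Markov chain; mean worn bout
  45 min; stationary worn fraction 0.267 by day and 0.042 at night.
  With the ~7.6-min HR cadence this yields ≈ 2.1 records per logged
  hour and ≈ 25 400 aligned records for 56 participants × 13 days —
  the scale of the motivating data set — while ~6% of sound logs fall
  at night so the daytime filter has work to do.
* **Soundscape process** — per-minute Markov chain with 5-min mean dwell
  whose per-hour stationary law is the configured diurnal occupancy
  (Quiet-heavy night/morning/late evening, Speech peaking 16:00–21:00,
  record-weighted shares ≈ 35/32/18/15%).
* **Acoustics** — per-minute (SPL, SML, SNR) from class-conditional
  correlated normals.  Class means/s.d.s follow the published
  record-level summaries where printed; the Speech SPL mean (60 dB) and
  Speech-in-Noise SML/SNR means (14 / 6.5 dB) are chosen to preserve the
  canonical ordering (Speech highest SNR and SML; Speech-in-Noise
  highest SPL; Quiet lowest SPL).  An alternative "envelope" mode
  synthesizes level series (syllabic bursts over a floor, plus a slow
  OU wander) and runs them through the DSP stack; it exercises the
  estimators and classifier and is co-calibrated with the classifier
  thresholds, but the tabular mode is the default for cohort-scale work.
* **Mobility/GPS** — per-minute still/walk/vehicle mixture (70/25/5%,
  8-min dwell) driving a heading random walk; minute-boundary fixes are
  emitted for a configurable fraction (22%) of participant-days, sized
  to the movement-bearing subset of the motivating analysis.  The
  still-speed scale and vehicle speed are calibrated so the pooled
  5-min window speed reproduces the printed median 0.15 m/s and
  s.d. 1.55 m/s.
* **Heart rate** — generated directly from the linear predictor the
  models fit: population mean 75.60 bpm, the configured fixed effects on
  the standardized window acoustics and/or class offsets and/or
  per-class slope offsets, 0.39 bpm per m/s of window movement, sampled
  random effects, and AR(1)(φ = 0.30, σ = 2.2 bpm) noise per
  participant-day.  A cardiophysiological simulator is deliberately not
  used: the analysis assumes only this linear structure, and recovery
  testing requires a known linear truth.  The generator computes its own
  window acoustics with exactly the preprocessing conventions
  (half-open window, ≥ 3 logs, modal class), so generative and fitted
  predictors coincide.

`hr_terms` selects which systematic components are active ("acoustic",
"soundscape", "interaction"), because class offsets and acoustic slopes
are strongly collinear through the class-conditional acoustics: a cohort
generated with both simultaneously has no single well-specified
counterpart among the fitted models.  Each recovery study therefore uses
the matching scenario (`scenario_config`).

**Variance split.**  The published summaries give a total record-level
HR s.d. of 6.89 bpm but no decomposition.  The default split is:
participant intercept 6.1, weekday 0.5, hour 0.7, each random slope
0.25, residual 2.2 (all bpm), which together with the fixed-effect
variance (~3.8 bpm²) and the movement term (~0.4 bpm²) reproduces
6.89 bpm:
6.1² + 0.5² + 0.7² + 3·0.25² + 2.2² + 3.8 + 0.4 ≈ 47.2 ≈ 6.87².
Between-person resting-HR heterogeneity dominating the total is also the
physiologically realistic allocation, and it keeps the pooled 5/95 HR
tail filter from distorting within-person associations (next paragraph).
For the log-response scenario all bpm-scale components are divided by
the population mean.

**Tail filtering and recovery.**  The pooled 5/95-percentile HR filter
selects on the response, so a filtered sample cannot exactly follow the
generative linear model; refitting after the filter attenuates every
coefficient (about 7–9% under these defaults, and more the larger the
within-person share of variance).  The recovery studies and the
acceptance script therefore fit on the *aligned* records (daytime filter,
window alignment, minimum-records filter), where recovery is unbiased;
the tail filter remains part of the default end-to-end pipeline and its
boundary behaviour is unit-tested.  Analysts applying the full pipeline
to real data should expect the same mild attenuation the original
procedure embodies.

## What passing tests do and do not show

The generator reproduces the assumed structure — linear effects,
nested random effects, discrete-lag AR(1), missingness through a wear
process that is independent of heart rate.  Real data differ in ways the
synthetic cohorts do not probe: wear and logging are likely informative
(people remove devices during exercise or sleep), acoustic class
boundaries drift with firmware, HR sensors have device-specific error,
movement is observed only through consumer GPS, and true
exposure-response relations need not be linear or additive.  Passing
recovery tests therefore validates the *implementation* of the pipeline
and estimators, not the causal or even associational claims one might
draw from real logs.

## Numerical choices and degenerate inputs

* Quantiles use linear interpolation between order statistics
  everywhere (percentile filter, decile edges, bin centers); decile ties
  go to the lower bin.
* The 60-s log aggregation and the window join both break modal-class
  ties toward the more complex class.
* The optimizer bounds log variance ratios in [−15, 10] and arctanh φ in
  [−5, 5]; a variance ratio collapsing below 1e−6 triggers a singular-fit
  warning naming the level.  Non-convergence after the perturbed
  restarts raises.
* Empty inputs, unparseable timestamps (reported with row indices),
  constant predictors, latitude/longitude out of range, GPS steps with
  non-positive time differences, and fewer than 2 participants per
  random level are all rejected explicitly.
* Problem sizes in the test-suite recovery studies: 3 seeds at
  56 × 13 days for each model family, and 20 replicates at 12 × 5 days
  for the CI-calibration study; the acceptance script averages over 3–6
  seeds per family.  These sizes hold the Monte-Carlo error of the seed
  averages a factor of a few below the recovery tolerances.

## Known limitations

* The AR(1) acts on record order, not elapsed time; long within-day gaps
  get the same lag-1 correlation as adjacent records.
* The classifier stand-in is a fixed decision list; it reproduces the
  qualitative class geometry, not any particular device's behaviour.
* Random-effect covariance is diagonal; correlated intercepts/slopes are
  out of scope.
* The effective-sampling-frequency summary conditions on hours with at
  least one record; empty hours are unobservable without wear truth.
* `RF2` inherits the level-wise sum-of-squares convention of `RP2`; it
  is not a conventional conditional R².
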