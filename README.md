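# hearbeat

Everyday ambient sound, as logged by hearing aids, and its short-term
association with heart rate from consumer wearables.

Internet-connected hearing aids can log a compact acoustic description of
the wearer's momentary sound environment every 60 s — broadband sound
pressure level (SPL), sound modulation level (SML, the spread between a
peak and a valley tracker of the level envelope), signal-to-noise ratio
(SNR, level above the running noise floor) and a discrete soundscape class
(Quiet / Speech / Speech-in-Noise / Noise) — while a paired wearable
reports a 5-min running-mean heart rate roughly every 7.6 min.  `hearbeat`
implements, as a tested and reusable pipeline, the statistical analysis
that links the two streams, and a synthetic-cohort generator with known
ground truth so that every stage can be validated by parameter recovery.

The package is aimed at researchers in ecological momentary physiology
and hearing science who want to reproduce, stress-test or extend this
kind of analysis without access to proprietary in-market data.

## The model

Each 5-min mean heart rate record \(y_{ptij}\) (participant *p*, weekday
*t*, hour *i*, record *j*) is joined with the arithmetic dB average of
each acoustic variable over the 5 minutes preceding it.  The core model
is a multi-level linear mixed-effects model

```
y = X beta + b_p + b_p,slope . z + b_pt + b_pi + e,      e ~ AR(1)(phi, sigma)
```

with fixed effects `beta` on the standardized (per 1 s.d.) window
acoustics or on soundscape class offsets versus Quiet, a random intercept
per participant, a random slope per continuous predictor per participant,
random intercepts for weekday and hour-of-day nested within participants,
and residuals following a first-order autoregressive process across
consecutive records within each participant-day.  Estimation is maximum
likelihood (REML optional) with the likelihood computed exactly via
per-participant AR(1) whitening and the Woodbury identity; no dense
covariance is ever formed.  Companion statistics include likelihood-ratio
tests, the generalized variance-inflation factor (GVIF), the partial
variance explained by the fixed effects for multilevel models,

```
RP2 = 1 - (sigma_F^2 + tau_F^2 + gamma_F^2) / (sigma_N^2 + tau_N^2 + gamma_N^2),
```

(level-wise residual sums-of-squares of the full versus an intercept-only
model with the identical random-effect law), slope contrasts of an
acoustics-by-soundscape interaction model, and the log-scale
back-transform `(exp(beta) - 1) * 100` giving percent HR change per dB.

Movement is handled by inverting GPS fixes through the haversine
great-circle distance into per-minute speeds, averaging them over the
same 5-min windows, excluding window means above cycling speed (10 m/s),
and either adjusting the models or estimating the HR-movement slope.

## Worked example

```python
from hearbeat import (scenario_config, simulate_cohort, build_records,
                      fit_model, ModelSpec)

cfg = scenario_config("acoustic", n_participants=8, n_days=4, seed=7)
cohort = simulate_cohort(cfg)                      # sound, HR and GPS logs
records, report = build_records(cohort.hr_logs, cohort.sound_logs,
                                cohort.gps_logs)   # aligned analysis records
fit = fit_model(records, ModelSpec(fixed="acoustic"))
print(fit.summary())
```

prints (abridged):

```
Mixed model: fixed='acoustic'  response='hr'  method=ML  AR(1)=True
n_obs=1072  participants=8  loglik=-2334.20  converged=True

term                          beta       se                95% CI
intercept                  +76.357    2.094   [ +72.252 to  +80.462]
spl                         +1.190    0.098   [  +0.999 to   +1.381]
sml                         +0.606    0.103   [  +0.404 to   +0.808]
snr                         -0.812    0.131   [  -1.068 to   -0.556]

variance components (s.d. in response units):
  participant               5.9160
  slope_spl                 0.1862
  slope_sml                 0.0373
  slope_snr                 0.2122
  weekday                   0.2571
  hour                      0.4111
  residual                  2.1232
  AR(1) phi                0.2730
```

The three acoustic coefficients are in bpm per 1 s.d. of the
window-averaged predictor.  The generating values for this cohort were
+1.47, +0.72 and -1.03 bpm per s.d.; at this deliberately small size
(8 participants, ~1000 records, and with the tail filter applied) the
estimates carry visible sampling error and mild attenuation, which is
why the recovery studies below use 56-participant cohorts.  The AR(1)
coefficient recovers the generative residual autocorrelation (0.30), and
the participant-level s.d. dominates the variance decomposition, as
configured.

A command-line interface wraps the same stages:

```
hearbeat simulate --participants 8 --days 4 --seed 7 --out logs/
hearbeat preprocess --hr logs/hr_logs.csv --sound logs/sound_logs.csv --out records.csv
hearbeat fit records.csv --model acoustic
hearbeat run --seed 7 --out full_run/     # simulate + preprocess + fit + describe
```

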