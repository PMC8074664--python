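"""Synthetic cohorts of sound, heart-rate and GPS logs with known truth.

The generator mirrors the structure the downstream analysis assumes, so
that fitting the analysis models to a simulated cohort is a parameter
recovery exercise:

* a per-minute **wear process** (two-state Markov chain with hour-dependent
  occupancy) gates when the hearing aid and wearable are connected —
  sound logs are emitted each worn minute, heart-rate logs at a jittered
  ~7.6 min cadence while worn;
* a per-minute **soundscape process** (Markov chain with configurable mean
  dwell whose per-hour stationary distribution follows the configured
  diurnal occupancy) and class-conditional correlated normal draws of
  (SPL, SML, SNR) in dB;
* a per-minute **mobility process** (still / walk / vehicle mixture) that
  drives a GPS random walk and contributes to heart rate through the
  5-min mean movement speed;
* heart rate generated directly from the linear model the analysis fits:
  population mean + fixed effects on the standardized 5-min window
  acoustics (and/or soundscape offsets, and/or per-class slope offsets)
  + movement effect + participant / weekday / hour random effects
  + a within participant-day AR(1) residual.

Heart rate is generated from the linear predictor, not from a
cardiophysiological simulator: the analysis only assumes the linear
structure it fits, and a known linear truth is what recovery tests need.

Randomness derives from one cohort seed, split per participant with
stable ``SeedSequence`` spawn keys, so outputs do not depend on iteration
order and are byte-identical across runs with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    ACOUSTIC_VARS,
    SOUNDSCAPES,
    ConfigError,
    GeneratorConfig,
    MobilityParams,
    config_to_dict,
)

__all__ = [
    "CohortData",
    "EnvelopeParams",
    "DEFAULT_ENVELOPES",
    "simulate_cohort",
    "scenario_config",
    "sample_soundscape_sequence",
    "synthesize_level_envelope",
    "generate_gps_track",
]

#: Cohort start date (a Monday inside the mid-2019 logging window).
BASE_DATE = pd.Timestamp("2019-06-03")

MIN_PER_DAY = 1440
_COLLAPSE = {"Quiet": "Quiet", "Speech": "Speech",
             "SpeechInNoise": "Noisy", "Noise": "Noisy"}


# --------------------------------------------------------------------------
# Public container
# --------------------------------------------------------------------------

@dataclass
class CohortData:
    """Everything one simulated cohort produced.

    ``truth_records`` has one row per emitted heart-rate log with the
    realized linear predictor and each of its components;
    ``truth`` holds the global ground-truth parameters (config echo,
    pooled standardization constants, per-participant random effects).
    """

    sound_logs: pd.DataFrame
    hr_logs: pd.DataFrame
    gps_logs: pd.DataFrame
    truth_records: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def write(self, outdir: str) -> dict[str, str]:
        """Write the three log tables as CSV and the truth as JSON."""
        import json
        import os

        os.makedirs(outdir, exist_ok=True)
        paths = {}
        for name, df in (("sound_logs", self.sound_logs), ("hr_logs", self.hr_logs),
                         ("gps_logs", self.gps_logs)):
            p = os.path.join(outdir, f"{name}.csv")
            df.to_csv(p, index=False, date_format="%Y-%m-%dT%H:%M:%S")
            paths[name] = p
        p = os.path.join(outdir, "truth.json")
        with open(p, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)
        paths["truth"] = p
        return paths


def scenario_config(scenario: str = "acoustic", **overrides) -> GeneratorConfig:
    """A :class:`GeneratorConfig` whose heart-rate model matches one analysis.

    ``scenario``:

    * ``"acoustic"`` — HR driven by standardized SPL/SML/SNR effects;
    * ``"soundscape"`` — HR driven by soundscape offsets versus Quiet;
    * ``"interaction"`` — acoustic slopes plus per-class slope offsets on
      the collapsed {Quiet, Speech, Noisy} soundscape;
    * ``"log"`` — log-scale HR with dB-scale percent-change effects.

    Keeping the generative model matched to the fitted model makes each
    recovery test well specified; components of the other scenarios would
    otherwise leak into the fitted coefficients through the correlation
    between soundscape class and acoustic level.
    """
    terms = {
        "acoustic": ("acoustic",),
        "soundscape": ("soundscape",),
        "interaction": ("acoustic", "interaction"),
        "log": ("acoustic",),
    }
    if scenario not in terms:
        raise ConfigError(f"scenario: unknown scenario {scenario!r}")
    kw = {"hr_terms": terms[scenario],
          "hr_response": "log" if scenario == "log" else "linear"}
    kw.update(overrides)
    cfg = GeneratorConfig(**kw)
    cfg.validate()
    return cfg


# --------------------------------------------------------------------------
# Markov helpers
# --------------------------------------------------------------------------

def _markov_binary(u: np.ndarray, p_off_to_on: np.ndarray,
                   p_on_to_off: float, init: np.ndarray) -> np.ndarray:
    """Vectorized two-state chain over lanes x steps; returns bool array."""
    lanes, steps = u.shape
    out = np.empty((lanes, steps), dtype=bool)
    state = init.copy()
    for t in range(steps):
        switch_on = (~state) & (u[:, t] < p_off_to_on[t])
        switch_off = state & (u[:, t] < p_on_to_off)
        state = np.where(state, ~switch_off, switch_on)
        out[:, t] = state
    return out


def sample_soundscape_sequence(hour_probabilities: np.ndarray, duration_minutes: int,
                               seed: int | None = None, dwell_minutes: float = 5.0,
                               start_hour: int = 0,
                               rng: np.random.Generator | None = None) -> np.ndarray:
    """Per-minute soundscape classes from an hour-modulated Markov chain.

    Each minute, with probability ``1/dwell_minutes`` the class is
    redrawn from the current hour's occupancy distribution, otherwise it
    persists.  Redrawing from the target distribution makes that
    distribution the stationary law of the chain within each hour, so
    long-run per-hour class frequencies match ``hour_probabilities``.

    Parameters
    ----------
    hour_probabilities : (24, 4) array
        Per-hour probabilities over (Quiet, Speech, SpeechInNoise, Noise);
        each row must sum to 1 within 1e-9.
    duration_minutes : int
        Length of the sequence.
    seed, rng
        Either a seed or an existing generator.

    Returns
    -------
    object ndarray of class names, length ``duration_minutes``.
    """
    occ = np.asarray(hour_probabilities, dtype=float)
    if occ.shape != (24, len(SOUNDSCAPES)):
        raise ConfigError(f"hour_probabilities: must have shape (24, {len(SOUNDSCAPES)})")
    if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("hour_probabilities: each hour must sum to 1 (tol 1e-9)")
    if np.any(occ < 0):
        raise ConfigError("hour_probabilities: probabilities must be >= 0")
    if dwell_minutes < 1:
        raise ConfigError("dwell_minutes: must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    cdf = np.cumsum(occ, axis=1)
    u_switch = rng.random(duration_minutes)
    u_pick = rng.random(duration_minutes)
    codes = np.empty(duration_minutes, dtype=np.int64)
    hour0 = start_hour % 24
    state = int(np.searchsorted(cdf[hour0], u_pick[0], side="right"))
    p_switch = 1.0 / dwell_minutes
    for t in range(duration_minutes):
        hour = (start_hour + t // 60) % 24
        if t == 0 or u_switch[t] < p_switch:
            state = int(np.searchsorted(cdf[hour], u_pick[t], side="right"))
        codes[t] = min(state, len(SOUNDSCAPES) - 1)
    return np.array(SOUNDSCAPES, dtype=object)[codes]


def _soundscape_minutes(rng: np.random.Generator, cdf: np.ndarray, n_days: int,
                        dwell: float) -> np.ndarray:
    """Class codes, shape (n_days, 1440); lanes are days of one participant."""
    u_switch = rng.random((n_days, MIN_PER_DAY))
    u_pick = rng.random((n_days, MIN_PER_DAY))
    out = np.empty((n_days, MIN_PER_DAY), dtype=np.int64)
    p_switch = 1.0 / dwell
    state = np.searchsorted(cdf[0], u_pick[:, 0], side="right")
    n_cls = cdf.shape[1]
    for t in range(MIN_PER_DAY):
        hour = (t // 60) % 24
        redraw = u_switch[:, t] < p_switch if t else np.ones(n_days, bool)
        drawn = np.searchsorted(cdf[hour], u_pick[:, t], side="right")
        state = np.where(redraw, drawn, state)
        out[:, t] = state
    return np.minimum(out, n_cls - 1)


# --------------------------------------------------------------------------
# Envelope synthesis (for exercising the DSP stack)
# --------------------------------------------------------------------------

@dataclass
class EnvelopeParams:
    """Shape of a class-typical level envelope in dB.

    The envelope is ``floor + depth * gate(t) + wander(t)``: bursts of
    ``depth`` dB above a floor at a syllabic ``rate_hz`` with duty cycle
    ``duty``, plus a slow Ornstein-Uhlenbeck level wander of s.d.
    ``wander_sd`` (time constant 2 s).  With ``depth = 0`` and
    ``wander_sd = 0`` the envelope is flat at the floor.
    """

    floor_db: float
    depth_db: float
    rate_hz: float
    duty: float = 0.5
    wander_sd: float = 1.0

    def validate(self) -> None:
        if not (0.0 <= self.duty <= 1.0):
            raise ConfigError("duty: must be in [0, 1]")
        if self.depth_db < 0 or self.wander_sd < 0:
            raise ConfigError("depth_db/wander_sd: must be >= 0")
        if self.rate_hz < 0:
            raise ConfigError("rate_hz: must be >= 0")


#: Co-tuned with the default :class:`~hearbeat.config.ClassifierThresholds`
#: so that frames of each envelope are predominantly classified as their
#: generating class: Quiet stays below the 52 dB gate; Speech carries deep
#: slow modulation over a low floor (high SML and SNR); Speech-in-Noise a
#: modulated signal over a high floor; Noise a high, nearly unmodulated floor.
DEFAULT_ENVELOPES: dict[str, EnvelopeParams] = {
    "Quiet": EnvelopeParams(floor_db=44.0, depth_db=6.0, rate_hz=2.0, duty=0.35,
                            wander_sd=1.0),
    "Speech": EnvelopeParams(floor_db=48.0, depth_db=26.0, rate_hz=4.0, duty=0.55,
                             wander_sd=1.0),
    "SpeechInNoise": EnvelopeParams(floor_db=59.0, depth_db=16.0, rate_hz=3.0, duty=0.5,
                                    wander_sd=0.8),
    "Noise": EnvelopeParams(floor_db=66.0, depth_db=3.0, rate_hz=8.0, duty=0.5,
                            wander_sd=0.8),
}


def synthesize_level_envelope(soundscape: str, duration_s: float,
                              params: EnvelopeParams | None = None,
                              seed: int | None = 0,
                              sample_rate: float = 100.0):
    """Generate a class-typical instantaneous level series.

    Parameters
    ----------
    soundscape : str
        One of Quiet, Speech, SpeechInNoise, Noise (selects default
        params when ``params`` is None).
    duration_s : float
        Length in seconds; must be > 0.
    sample_rate : float
        Must be at least 20 Hz to resolve the 30 ms tracker release.

    Returns
    -------
    :class:`~hearbeat.features.LevelSeries`
    """
    from .features import LevelSeries

    if soundscape not in SOUNDSCAPES:
        raise ConfigError(f"soundscape: unknown class {soundscape!r}")
    if duration_s <= 0:
        raise ConfigError("duration_s: must be > 0")
    if sample_rate < 20:
        raise ConfigError("sample_rate: must be >= 20 Hz")
    p = params or DEFAULT_ENVELOPES[soundscape]
    p.validate()
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate

    # Syllabic gating with a slowly drifting phase.
    phase_jitter = np.cumsum(rng.normal(0.0, 0.01, size=n))
    phase = (p.rate_hz * t + rng.random() + phase_jitter) % 1.0
    gate = (phase < p.duty).astype(float) if p.depth_db > 0 else np.zeros(n)

    # OU wander, time constant 2 s, stationary s.d. wander_sd.
    wander = np.zeros(n)
    if p.wander_sd > 0:
        a = np.exp(-1.0 / (2.0 * sample_rate))
        innov = rng.normal(0.0, p.wander_sd * np.sqrt(1 - a * a), size=n)
        prev = rng.normal(0.0, p.wander_sd)
        for i in range(n):
            prev = a * prev + innov[i]
            wander[i] = prev

    return LevelSeries(sample_rate=sample_rate,
                       values=p.floor_db + p.depth_db * gate + wander)


# --------------------------------------------------------------------------
# Mobility / GPS
# --------------------------------------------------------------------------

def _mobility_minutes(rng: np.random.Generator, mp: MobilityParams,
                      n_days: int) -> np.ndarray:
    """True per-minute speeds (m/s), shape (n_days, 1440)."""
    probs = np.asarray(mp.state_probs)
    cdf = np.cumsum(probs)
    u_switch = rng.random((n_days, MIN_PER_DAY))
    u_pick = rng.random((n_days, MIN_PER_DAY))
    state = np.searchsorted(cdf, u_pick[:, 0], side="right")
    states = np.empty((n_days, MIN_PER_DAY), dtype=np.int64)
    p_switch = 1.0 / mp.dwell_minutes
    for t in range(MIN_PER_DAY):
        redraw = u_switch[:, t] < p_switch if t else np.ones(n_days, bool)
        drawn = np.searchsorted(cdf, u_pick[:, t], side="right")
        state = np.where(redraw, drawn, state)
        states[:, t] = state
    states = np.minimum(states, 2)

    speed = np.empty((n_days, MIN_PER_DAY))
    z = rng.standard_normal((n_days, MIN_PER_DAY))
    speed = np.where(states == 0, np.abs(z) * mp.still_speed_scale,
                     np.where(states == 1,
                              np.clip(mp.walk_speed_mean + z * mp.walk_speed_sd, 0, None),
                              np.clip(mp.vehicle_speed_mean + z * mp.vehicle_speed_sd,
                                      0, None)))
    if mp.fast_fraction > 0:
        fast = rng.random((n_days, MIN_PER_DAY)) < mp.fast_fraction
        speed = np.where(fast, rng.uniform(10.5, 18.0, size=speed.shape), speed)
    return speed


def _integrate_track(rng: np.random.Generator, speed: np.ndarray,
                     lat0: float, lon0: float,
                     earth_radius: float = 6_371_000.0) -> tuple[np.ndarray, np.ndarray]:
    """GPS fixes at minute boundaries from per-minute speeds and headings.

    Returns (lat, lon) of shape (n_days, 1441): fix ``m`` is the position
    at the start of minute ``m``; the haversine distance between fixes
    ``m`` and ``m+1`` equals ``speed[m] * 60`` up to spherical curvature.
    """
    n_days, m = speed.shape
    heading = np.cumsum(rng.normal(0.0, 0.5, size=(n_days, m)), axis=1) \
        + rng.uniform(0, 2 * np.pi, size=(n_days, 1))
    disp = speed * 60.0
    dn = disp * np.cos(heading)
    de = disp * np.sin(heading)
    deg = 180.0 / np.pi
    dlat = dn / earth_radius * deg
    dlon = de / (earth_radius * np.cos(np.radians(lat0))) * deg
    lat = np.concatenate([np.full((n_days, 1), lat0), lat0 + np.cumsum(dlat, axis=1)],
                         axis=1)
    lon = np.concatenate([np.full((n_days, 1), lon0), lon0 + np.cumsum(dlon, axis=1)],
                         axis=1)
    return lat, lon


def generate_gps_track(participant_id: str = "P000", day: int = 0,
                       mobility_params: MobilityParams | None = None,
                       seed: int | None = 0,
                       start: tuple[float, float] = (55.7, 12.5)) -> pd.DataFrame:
    """One participant-day GPS track at 60-s cadence.

    Returns a DataFrame with ``participant_id, timestamp, latitude,
    longitude`` and, for convenience of testing, the true per-minute speed
    ``speed_true`` of the minute *starting* at each fix (NaN on the last).
    """
    mp = mobility_params or MobilityParams()
    mp.validate()
    rng = np.random.default_rng(seed)
    speed = _mobility_minutes(rng, mp, 1)
    lat, lon = _integrate_track(rng, speed, start[0], start[1])
    t0 = BASE_DATE + pd.Timedelta(days=day)
    ts = t0 + pd.to_timedelta(np.arange(MIN_PER_DAY + 1) * 60, unit="s")
    return pd.DataFrame({
        "participant_id": participant_id,
        "timestamp": ts,
        "latitude": lat[0],
        "longitude": lon[0],
        "speed_true": np.concatenate([speed[0], [np.nan]]),
    })


# --------------------------------------------------------------------------
# Cohort simulation
# --------------------------------------------------------------------------

def _window_stats(times_s: np.ndarray, values: np.ndarray, codes: np.ndarray,
                  rec_times: np.ndarray, window: float, n_classes: int):
    """Per-record half-open window (t - window, t] means, counts and mode."""
    lo = np.searchsorted(times_s, rec_times - window, side="right")
    hi = np.searchsorted(times_s, rec_times, side="right")
    n = hi - lo
    safe = np.maximum(n, 1)
    means = np.empty((rec_times.size, values.shape[1]))
    for j in range(values.shape[1]):
        c = np.concatenate([[0.0], np.cumsum(values[:, j])])
        means[:, j] = (c[hi] - c[lo]) / safe
    counts = np.empty((rec_times.size, n_classes), dtype=np.int64)
    for k in range(n_classes):
        c = np.concatenate([[0], np.cumsum(codes == k)])
        counts[:, k] = c[hi] - c[lo]
    # mode with ties to the more complex class (higher code)
    mode = (n_classes - 1) - np.argmax(counts[:, ::-1], axis=1)
    return n, means, mode


def _wear_minutes(rng: np.random.Generator, cfg: GeneratorConfig,
                  n_days: int) -> np.ndarray:
    hours = (np.arange(MIN_PER_DAY) // 60) % 24
    day_mask = (hours >= 6) & (hours < 24)
    pi = np.where(day_mask, cfg.wear_on_fraction_day, cfg.wear_on_fraction_night)
    q = 1.0 / cfg.wear_bout_minutes
    r = q * pi / np.maximum(1.0 - pi, 1e-12)
    u = rng.random((n_days, MIN_PER_DAY))
    init = rng.random(n_days) < pi[0]
    return _markov_binary(u, r, q, init)


def simulate_cohort(config: GeneratorConfig | None = None) -> CohortData:
    """Simulate a full cohort of sound, heart-rate and GPS logs.

    The simulation proceeds in two passes: first every participant's
    minute-level processes (wear, soundscape, acoustics, mobility) and
    candidate heart-rate times are drawn; then, after pooling the 5-min
    window acoustics across the cohort to fix the standardization
    constants, heart rate is assembled from the configured linear
    predictor plus sampled random effects and AR(1) noise.  All sampling
    within a participant uses that participant's own child generator, so
    the output is deterministic for a given config and seed.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()

    chol = {}
    corr = np.asarray(cfg.acoustic_corr, dtype=float)
    for cls in SOUNDSCAPES:
        sd = np.asarray(cfg.class_acoustics[cls]["sd"], dtype=float)
        cov = corr * np.outer(sd, sd)
        chol[cls] = np.linalg.cholesky(cov + 1e-12 * np.eye(3))

    occ_cdf = np.cumsum(np.asarray(cfg.diurnal_occupancy, dtype=float), axis=1)
    n_cls = len(SOUNDSCAPES)
    cls_arr = np.array(SOUNDSCAPES, dtype=object)

    parts = []
    for pidx in range(cfg.n_participants):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(pidx,)))
        pid = f"P{pidx:03d}"
        nd = cfg.n_days

        worn = _wear_minutes(rng, cfg, nd)                       # (nd, 1440)
        codes = _soundscape_minutes(rng, occ_cdf, nd, cfg.soundscape_dwell_minutes)
        z = rng.standard_normal((nd, MIN_PER_DAY, 3))
        acou = np.empty((nd, MIN_PER_DAY, 3))
        for k, cls in enumerate(SOUNDSCAPES):
            mask = codes == k
            mean = np.asarray(cfg.class_acoustics[cls]["mean"], dtype=float)
            acou[mask] = mean + z[mask] @ chol[cls].T

        if cfg.simulate_gps:
            speed = _mobility_minutes(rng, cfg.mobility, nd)
            gps_days = rng.random(nd) < cfg.gps_fraction
            lat0 = 55.7 + rng.normal(0, 0.02)
            lon0 = 12.5 + rng.normal(0, 0.03)
            lat, lon = _integrate_track(rng, speed, lat0, lon0)
        else:
            speed = np.zeros((nd, MIN_PER_DAY))
            gps_days = np.zeros(nd, dtype=bool)
            lat = lon = None

        # Candidate HR times: jittered intervals, kept while worn.
        n_iv = int(86400 / max(cfg.hr_log_period_mean, 61.0)) + 30
        iv = np.maximum(60.0, rng.normal(cfg.hr_log_period_mean,
                                         cfg.hr_log_period_sd, size=(nd, n_iv)))
        tt = np.cumsum(iv, axis=1)
        day_idx, k_idx = np.nonzero(tt < 86400.0)
        tsec = tt[day_idx, k_idx]
        minute = (tsec // 60).astype(int)
        keep = worn[day_idx, minute]
        # round to whole seconds up front so the emitted timestamps and the
        # window arithmetic of the truth agree exactly with the pipeline's
        hr_day, hr_sec = day_idx[keep], np.round(tsec[keep])

        # Flatten worn minutes into this participant's sound log table.
        wday, wmin = np.nonzero(worn)
        snd_sec = wday * 86400.0 + wmin * 60.0
        parts.append({
            "pidx": pidx, "pid": pid, "rng": rng,
            "snd_sec": snd_sec, "snd_vals": acou[wday, wmin],
            "snd_codes": codes[wday, wmin],
            "hr_day": hr_day, "hr_sec": hr_day * 86400.0 + hr_sec,
            "speed_flat": speed.ravel(), "gps_days": gps_days,
            "lat": lat, "lon": lon,
        })

    # ---- pass 2a: window acoustics per HR log, pooled standardization ----
    window = 300.0
    pooled = []
    for P in parts:
        n_w, means, mode = _window_stats(P["snd_sec"], P["snd_vals"], P["snd_codes"],
                                         P["hr_sec"], window, n_cls)
        # movement: step ending at minute boundary (m+1)*60 carries speed[m]
        step_end = (np.arange(P["speed_flat"].size) + 1) * 60.0
        lo = np.searchsorted(step_end, P["hr_sec"] - window, side="right")
        hi = np.searchsorted(step_end, P["hr_sec"], side="right")
        csum = np.concatenate([[0.0], np.cumsum(P["speed_flat"])])
        mv = (csum[hi] - csum[lo]) / np.maximum(hi - lo, 1)
        P.update(n_window=n_w, win_means=means, win_mode=mode, movement=mv)
        hour = ((P["hr_sec"] % 86400.0) // 3600).astype(int)
        eligible = (n_w >= 3) & (hour >= 6)
        P["hour"] = hour
        pooled.append(means[eligible])
    pooled = np.vstack([p for p in pooled if len(p)]) if pooled else np.zeros((0, 3))
    if len(pooled) == 0:
        raise RuntimeError("simulation produced no eligible heart-rate windows")
    pool_mean = pooled.mean(axis=0)
    pool_sd = pooled.std(axis=0, ddof=0)
    pool_sd[pool_sd == 0] = 1.0

    # ---- pass 2b: random effects, AR(1) noise, heart rate ---------------
    log_scale = cfg.hr_response == "log"
    base = np.log(cfg.population_hr_mean) if log_scale else cfg.population_hr_mean
    unit = 1.0 / cfg.population_hr_mean if log_scale else 1.0   # bpm -> response units
    fe = np.array([cfg.fixed_effects.get(v, 0.0) for v in ACOUSTIC_VARS])
    fe_log = np.array([cfg.log_fixed_effects.get(v, 0.0) for v in ACOUSTIC_VARS])
    rsd = cfg.random_sd

    sound_frames, hr_frames, gps_frames, truth_frames = [], [], [], []
    re_truth = {}
    for P in parts:
        rng = P["rng"]
        b0 = rng.normal(0.0, rsd.get("participant", 0.0))
        bslope = np.array([rng.normal(0.0, rsd.get(f"slope_{v}", 0.0))
                           for v in ACOUSTIC_VARS])
        bwd = rng.normal(0.0, rsd.get("weekday", 0.0), size=7)
        bhr = rng.normal(0.0, rsd.get("hour", 0.0), size=24)
        re_truth[P["pid"]] = {"intercept": b0,
                              "slopes": dict(zip(ACOUSTIC_VARS, bslope)),
                              "weekday": bwd.tolist(), "hour": bhr.tolist()}

        nrec = P["hr_sec"].size
        zrec = (P["win_means"] - pool_mean) / pool_sd
        mode_names = cls_arr[P["win_mode"]]
        eta = np.full(nrec, base + b0 * unit)
        if "acoustic" in cfg.hr_terms:
            if log_scale:
                eta += (P["win_means"] - pool_mean) @ fe_log
            else:
                eta += zrec @ fe
        if "soundscape" in cfg.hr_terms:
            off = np.array([cfg.soundscape_effects.get(c, 0.0) for c in mode_names])
            eta += off * unit
        if "interaction" in cfg.hr_terms:
            collapsed = np.array([_COLLAPSE[c] for c in mode_names], dtype=object)
            off = np.array([cfg.collapsed_soundscape_effects.get(c, 0.0)
                            for c in collapsed])
            delta = np.zeros((nrec, 3))
            for j, v in enumerate(ACOUSTIC_VARS):
                for c in ("Speech", "Noisy"):
                    delta[collapsed == c, j] = cfg.interaction_effects.get((c, v), 0.0)
            eta += (off + np.sum(delta * zrec, axis=1)) * unit
        eta += (zrec @ bslope) * unit
        if cfg.simulate_gps:
            eta += cfg.movement_effect * P["movement"] * unit
        dates = BASE_DATE + pd.to_timedelta(P["hr_day"], unit="D")
        wd = dates.weekday.to_numpy() if hasattr(dates, "weekday") else \
            np.array([d.weekday() for d in dates])
        eta += (bwd[wd] + bhr[P["hour"]]) * unit

        # AR(1) residual within each participant-day, record order.
        eps = np.zeros(nrec)
        sig = cfg.residual_sd * unit
        if sig > 0:
            nu = rng.standard_normal(nrec)
            phi = cfg.ar1_phi
            prev_day = -1
            prev_e = 0.0
            for i in range(nrec):
                if P["hr_day"][i] != prev_day:
                    prev_e = sig * nu[i]
                    prev_day = P["hr_day"][i]
                else:
                    prev_e = phi * prev_e + np.sqrt(1 - phi * phi) * sig * nu[i]
                eps[i] = prev_e
        eta_total = eta + eps
        hr = np.exp(eta_total) if log_scale else eta_total

        ts_hr = BASE_DATE + pd.to_timedelta(np.round(P["hr_sec"]).astype(np.int64),
                                            unit="s")
        hr_frames.append(pd.DataFrame({
            "participant_id": P["pid"], "timestamp": ts_hr, "hr": hr}))
        ts_snd = BASE_DATE + pd.to_timedelta(P["snd_sec"].astype(np.int64), unit="s")
        sound_frames.append(pd.DataFrame({
            "participant_id": P["pid"], "timestamp": ts_snd,
            "spl": P["snd_vals"][:, 0], "sml": P["snd_vals"][:, 1],
            "snr": P["snd_vals"][:, 2], "soundscape": cls_arr[P["snd_codes"]]}))
        if cfg.simulate_gps and P["gps_days"].any():
            gd = np.flatnonzero(P["gps_days"])
            gsec = (gd[:, None] * 86400 + np.arange(MIN_PER_DAY) * 60).ravel()
            glat = P["lat"][gd, :MIN_PER_DAY].ravel()
            glon = P["lon"][gd, :MIN_PER_DAY].ravel()
            gps_frames.append(pd.DataFrame({
                "participant_id": P["pid"],
                "timestamp": BASE_DATE + pd.to_timedelta(gsec, unit="s"),
                "latitude": glat, "longitude": glon}))
        truth_frames.append(pd.DataFrame({
            "participant_id": P["pid"], "timestamp": ts_hr, "day": P["hr_day"],
            "n_window_logs": P["n_window"],
            "z_spl": zrec[:, 0], "z_sml": zrec[:, 1], "z_snr": zrec[:, 2],
            "soundscape": mode_names, "movement_true": P["movement"],
            "eta": eta_total, "eta_systematic": eta, "hr": hr,
            "eligible": (P["n_window"] >= 3) & (P["hour"] >= 6)}))

    empty_gps = pd.DataFrame(columns=["participant_id", "timestamp",
                                      "latitude", "longitude"])
    cohort = CohortData(
        sound_logs=pd.concat(sound_frames, ignore_index=True),
        hr_logs=pd.concat(hr_frames, ignore_index=True),
        gps_logs=(pd.concat(gps_frames, ignore_index=True)
                  if gps_frames else empty_gps),
        truth_records=pd.concat(truth_frames, ignore_index=True),
        truth={
            "config": config_to_dict(cfg),
            "standardization": {"mean": dict(zip(ACOUSTIC_VARS, pool_mean)),
                                "sd": dict(zip(ACOUSTIC_VARS, pool_sd))},
            "random_effects": re_truth,
        },
    )
    return cohort
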