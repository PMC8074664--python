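"""Broadband acoustic estimators emulating in-device hearing-aid logging.

A hearing aid observes an instantaneous broadband level (dB SPL vs time).
From it the device derives, every sample:

* **SPL** — the level smoothed by a one-pole low-pass IIR filter with a
  63 ms time constant;
* **top / bottom trackers** — asymmetric one-pole followers acting as peak
  and valley detectors of the SPL (slow attack of a few seconds, fast
  30 ms release, mirrored between the two);
* **SML** (sound modulation level) — top minus bottom tracker, a measure
  of amplitude-modulation depth;
* **SNR** — immediate SPL minus the bottom tracker, i.e. signal level
  above the running noise floor;
* a discrete **soundscape** class (Quiet / Speech / Speech-in-Noise /
  Noise) from a threshold decision list over (SPL, SML, SNR).

All processing operates directly on dB-domain levels: every quantity of
interest is a difference of level trackers, so the linear-pressure domain
is never needed.  Frames are aggregated to 60-s logs by arithmetic dB mean
with a modal class (complexity-ordered tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SOUNDSCAPES, ClassifierThresholds, TrackerConfig

__all__ = [
    "LevelSeries",
    "estimate_spl",
    "track_extrema",
    "derive_sml_snr",
    "classify_soundscape",
    "compute_frames",
    "log_sound",
]


@dataclass
class LevelSeries:
    """An instantaneous broadband level series in dB SPL.

    Attributes
    ----------
    sample_rate : float
        Samples per second; must be positive.
    values : ndarray
        Level in dB at each sample; must be finite.
    """

    sample_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


def _alpha(dt: float, tau: float) -> float:
    # Smoothing weight of a one-pole filter integrated over one sample.
    return 1.0 - np.exp(-dt / tau)


def estimate_spl(series: LevelSeries, spl_tau: float = 0.063) -> np.ndarray:
    """Smooth an instantaneous level with a one-pole low-pass IIR filter.

    Implements ``y[n] = y[n-1] + alpha * (x[n] - y[n-1])`` with
    ``alpha = 1 - exp(-dt/tau)``, initialized at ``x[0]``.

    Parameters
    ----------
    series : LevelSeries
        Input level series; must be non-empty.
    spl_tau : float
        Filter time constant in seconds (63 ms by default).

    Returns
    -------
    ndarray of the same length as the input.
    """
    if series.values.size == 0:
        raise ValueError("cannot estimate SPL of an empty series")
    if spl_tau <= 0:
        raise ValueError("spl_tau must be > 0")
    x = series.values
    a = _alpha(series.dt, spl_tau)
    # One-pole recursion via scipy's IIR machinery: y[n] = (1-a) y[n-1] + a x[n].
    from scipy.signal import lfilter, lfiltic

    zi = lfiltic([a], [1.0, -(1.0 - a)], y=[x[0]], x=[x[0]])
    y, _ = lfilter([a], [1.0, -(1.0 - a)], x, zi=zi)
    return y


def _asym_follow(x: np.ndarray, alpha_rise: float, alpha_fall: float) -> np.ndarray:
    """One-pole follower with different weights for rising/falling input."""
    y = np.empty_like(x)
    state = x[0]
    y[0] = state
    for n in range(1, x.size):
        a = alpha_rise if x[n] > state else alpha_fall
        state = state + a * (x[n] - state)
        y[n] = state
    return y


def track_extrema(spl: np.ndarray, sample_rate: float,
                  config: TrackerConfig | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Run the top (peak) and bottom (valley) trackers over an SPL series.

    The bottom tracker drops quickly when the input falls below its state
    (release, 30 ms) and recovers slowly when the input rises above it
    (attack, seconds); the top tracker mirrors this.  Both are initialized
    at ``spl[0]``, which guarantees ``top >= bottom`` pointwise.

    Returns
    -------
    (top, bottom) : tuple of ndarray
    """
    config = config or TrackerConfig()
    config.validate()
    spl = np.asarray(spl, dtype=float)
    if spl.size == 0:
        raise ValueError("cannot track an empty series")
    dt = 1.0 / sample_rate
    bottom = _asym_follow(spl, _alpha(dt, config.bottom_rise_tau),
                          _alpha(dt, config.bottom_fall_tau))
    top = _asym_follow(spl, _alpha(dt, config.top_rise_tau),
                       _alpha(dt, config.top_fall_tau))
    return top, bottom


def derive_sml_snr(spl: np.ndarray, top: np.ndarray,
                   bottom: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Derive SML and SNR series from the SPL and its trackers.

    ``sml = top - bottom`` (non-negative by the tracker construction) and
    ``snr = spl - bottom``, signed so that signal above the noise floor is
    positive.
    """
    spl, top, bottom = (np.asarray(a, dtype=float) for a in (spl, top, bottom))
    if not (spl.shape == top.shape == bottom.shape):
        raise ValueError("spl, top and bottom must have equal lengths")
    return top - bottom, spl - bottom


def classify_soundscape(spl, sml, snr,
                        thresholds: ClassifierThresholds | None = None):
    """Classify frames into Quiet / Speech / SpeechInNoise / Noise.

    Decision list: Quiet if ``spl < quiet_spl_max``; else Speech if the
    frame is both clean (``snr >= speech_snr_min``) and strongly modulated
    (``sml >= speech_sml_min``); else Speech-in-Noise under the relaxed
    thresholds; else Noise.  Total and deterministic on finite inputs.

    Accepts scalars or arrays; returns a string or an object array.
    """
    th = thresholds or ClassifierThresholds()
    th.validate()
    spl = np.asarray(spl, dtype=float)
    sml = np.asarray(sml, dtype=float)
    snr = np.asarray(snr, dtype=float)
    scalar = spl.ndim == 0
    spl, sml, snr = np.atleast_1d(spl), np.atleast_1d(sml), np.atleast_1d(snr)
    if not (np.all(np.isfinite(spl)) and np.all(np.isfinite(sml)) and np.all(np.isfinite(snr))):
        raise ValueError("classifier inputs must be finite")
    out = np.full(spl.shape, "Noise", dtype=object)
    sin_mask = (snr >= th.sin_snr_min) & (sml >= th.sin_sml_min)
    out[sin_mask] = "SpeechInNoise"
    speech_mask = (snr >= th.speech_snr_min) & (sml >= th.speech_sml_min)
    out[speech_mask] = "Speech"
    out[spl < th.quiet_spl_max] = "Quiet"
    return out[0] if scalar else out


def compute_frames(series: LevelSeries,
                   tracker: TrackerConfig | None = None,
                   thresholds: ClassifierThresholds | None = None,
                   frame_period: float = 1.0) -> pd.DataFrame:
    """Full estimator chain producing classified acoustic frames.

    The per-sample estimators (SPL smoother, top/bottom trackers, SML and
    SNR) run at the native sample rate; their outputs are then summarized
    into frames of ``frame_period`` seconds (arithmetic dB means) and each
    frame is classified.  One-second frames decouple the classifier from
    the fast syllabic oscillation of the instantaneous SPL.

    Returns a DataFrame with columns ``time_s, spl, sml, snr, soundscape``
    (``time_s`` is the frame start).
    """
    tracker = tracker or TrackerConfig()
    if frame_period <= 0:
        raise ValueError("frame_period must be > 0")
    spl = estimate_spl(series, tracker.spl_tau)
    top, bottom = track_extrema(spl, series.sample_rate, tracker)
    sml, snr = derive_sml_snr(spl, top, bottom)
    bucket = np.floor(series.times / frame_period + 1e-12).astype(int)
    df = pd.DataFrame({"bucket": bucket, "spl": spl, "sml": sml, "snr": snr})
    agg = df.groupby("bucket", sort=True).mean()
    frames = pd.DataFrame({
        "time_s": agg.index.to_numpy() * frame_period,
        "spl": agg["spl"].to_numpy(),
        "sml": agg["sml"].to_numpy(),
        "snr": agg["snr"].to_numpy(),
    })
    frames["soundscape"] = classify_soundscape(
        frames["spl"], frames["sml"], frames["snr"], thresholds)
    return frames


def modal_class(classes) -> str:
    """Most frequent soundscape; ties go to the more complex class.

    Complexity order: Quiet < Speech < SpeechInNoise < Noise.
    """
    classes = list(classes)
    if not classes:
        raise ValueError("cannot take the mode of an empty class sequence")
    counts = {c: 0 for c in SOUNDSCAPES}
    for c in classes:
        counts[c] += 1
    best = max(SOUNDSCAPES, key=lambda c: (counts[c], SOUNDSCAPES.index(c)))
    return best


def log_sound(frames: pd.DataFrame, period: float = 60.0) -> pd.DataFrame:
    """Aggregate per-sample frames into fixed-period sound logs.

    One record per period containing the arithmetic dB mean of spl/sml/snr
    and the modal soundscape (complexity-ordered tie-break).  Periods with
    no frames produce no record.

    Parameters
    ----------
    frames : DataFrame
        Output of :func:`compute_frames` (needs ``time_s, spl, sml, snr,
        soundscape``).
    period : float
        Logging period in seconds (default 60).
    """
    if period <= 0:
        raise ValueError("period must be > 0")
    if len(frames) == 0:
        raise ValueError("frames must span at least one logging period")
    t = frames["time_s"].to_numpy(float)
    dt = float(np.median(np.diff(t))) if len(t) > 1 else period
    if t[-1] - t[0] + dt < period - 1e-9:
        raise ValueError("frames must span at least one logging period")
    bucket = np.floor(frames["time_s"].to_numpy() / period).astype(int)
    out = []
    for b in np.unique(bucket):
        sel = frames.loc[bucket == b]
        out.append({
            "time_s": b * period,
            "spl": sel["spl"].mean(),
            "sml": sel["sml"].mean(),
            "snr": sel["snr"].mean(),
            "soundscape": modal_class(sel["soundscape"]),
        })
    return pd.DataFrame(out)
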