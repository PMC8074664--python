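"""Building analysis records from raw sound, heart-rate and GPS logs.

The statistical analysis consumes *data records*: one 5-min running-mean
heart-rate sample joined with the arithmetic dB average of every acoustic
variable over the 5 minutes preceding it, the modal soundscape of that
window, and (when GPS is present) the mean movement speed in the window.

Filtration rules, in fixed order:

1. daytime filter — only logs between 06:00 and 24:00 local time;
2. window alignment — half-open window ``(t - 300 s, t]`` before each HR
   log, requiring at least ``min_window_logs`` sound logs;
3. pooled heart-rate percentile filter — records strictly below the 5th or
   strictly above the 95th percentile of the pooled HR are dropped;
4. participant filter — participants with fewer than 50 surviving records
   are dropped entirely.

Movement is estimated from consecutive GPS fixes with the haversine
great-circle formula, divided by the time step, averaged over the same
5-min window, filtered at cycling speed (10 m/s) on the *window mean*, and
assigned to pooled deciles.

Every stage reports counts in/out/dropped in a :class:`FiltrationReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SOUNDSCAPES, PreprocessConfig

__all__ = [
    "FiltrationReport",
    "filter_daytime",
    "align_records",
    "filter_hr_percentiles",
    "filter_min_records",
    "effective_sampling_frequency",
    "haversine_distance",
    "movement_speed",
    "build_records",
]


@dataclass
class FiltrationReport:
    """Per-stage accounting of records entering, surviving and dropped."""

    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        assert n_out <= n_in
        self.stages.append({"stage": stage, "in": n_in, "out": n_out,
                            "dropped": n_in - n_out, **extra})

    def to_dict(self) -> dict:
        return {"stages": self.stages}


def _parse_timestamps(df: pd.DataFrame) -> pd.Series:
    ts = pd.to_datetime(df["timestamp"], errors="coerce")
    bad = ts.isna()
    if bad.any():
        rows = df.index[bad].tolist()[:5]
        raise ValueError(f"unparseable timestamps at rows {rows}")
    return ts


def filter_daytime(logs: pd.DataFrame, config: PreprocessConfig | None = None,
                   report: FiltrationReport | None = None) -> pd.DataFrame:
    """Keep logs with local clock time in [day_start, day_end).

    With the defaults this keeps [06:00, 24:00): a log at 05:59:59 is
    dropped, one at exactly 06:00:00 is kept.  Order is preserved.
    """
    config = config or PreprocessConfig()
    config.validate()
    if len(logs) == 0:
        return logs.copy()
    ts = _parse_timestamps(logs)
    seconds = ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second
    keep = (seconds >= config.day_start_hour * 3600) & (seconds < config.day_end_hour * 3600)
    out = logs.loc[keep].copy()
    if report is not None:
        report.add("daytime_filter", len(logs), len(out))
    return out


def align_records(hr_logs: pd.DataFrame, sound_logs: pd.DataFrame,
                  config: PreprocessConfig | None = None,
                  report: FiltrationReport | None = None) -> pd.DataFrame:
    """Join each HR log with the acoustics of its preceding 5-min window.

    For each HR log at time ``t`` the sound logs of the same participant
    with timestamps in the half-open window ``(t - window, t]`` are
    averaged (arithmetic dB mean) and their modal soundscape is taken
    (ties to the more complex class).  Windows with fewer than
    ``min_window_logs`` sound logs yield no record; skips are counted in
    the report.

    Returns a DataFrame with one row per retained HR log and columns
    ``participant_id, timestamp, hr, spl, sml, snr, soundscape,
    n_window_logs, date, weekday, hour``.
    """
    config = config or PreprocessConfig()
    config.validate()
    hr = hr_logs.copy()
    hr["__ts"] = _parse_timestamps(hr_logs)
    snd = sound_logs.copy()
    snd["__ts"] = _parse_timestamps(sound_logs)

    # Tie-break order for the window mode: scan classes from most to least
    # complex so that argmax (first maximum) lands on the more complex one.
    complexity_desc = list(SOUNDSCAPES[::-1])

    chunks = []
    n_skipped = 0
    for pid, hr_p in hr.groupby("participant_id", sort=True):
        snd_p = snd.loc[snd["participant_id"] == pid].sort_values("__ts")
        st = snd_p["__ts"].to_numpy(dtype="datetime64[ns]")
        hr_p = hr_p.sort_values("__ts")
        rt = hr_p["__ts"].to_numpy(dtype="datetime64[ns]")
        t0 = rt - np.timedelta64(int(config.window_seconds * 1e9), "ns")
        lo = np.searchsorted(st, t0, side="right")   # exclude t - window
        hi = np.searchsorted(st, rt, side="right")   # include t
        n = hi - lo
        keep = n >= config.min_window_logs
        n_skipped += int((~keep).sum())
        if not keep.any():
            continue
        lo, hi, n = lo[keep], hi[keep], n[keep]
        hr_k = hr_p.loc[keep]
        # Window means via prefix sums; window mode via per-class prefix counts.
        means = {}
        for var in ("spl", "sml", "snr"):
            csum = np.concatenate([[0.0], np.cumsum(snd_p[var].to_numpy(float))])
            means[var] = (csum[hi] - csum[lo]) / n
        cls = snd_p["soundscape"].to_numpy(object)
        counts = np.empty((len(lo), len(complexity_desc)), dtype=np.int64)
        for j, c in enumerate(complexity_desc):
            ccum = np.concatenate([[0], np.cumsum(cls == c)])
            counts[:, j] = ccum[hi] - ccum[lo]
        mode = np.array(complexity_desc, dtype=object)[np.argmax(counts, axis=1)]
        ts = pd.DatetimeIndex(hr_k["__ts"])
        chunks.append(pd.DataFrame({
            "participant_id": pid,
            "timestamp": hr_k["timestamp"].to_numpy(),
            "hr": hr_k["hr"].to_numpy(float),
            "spl": means["spl"], "sml": means["sml"], "snr": means["snr"],
            "soundscape": mode,
            "n_window_logs": n,
            "date": ts.strftime("%Y-%m-%d"),
            "weekday": ts.weekday,
            "hour": ts.hour,
        }))
    cols = ["participant_id", "timestamp", "hr", "spl", "sml", "snr", "soundscape",
            "n_window_logs", "date", "weekday", "hour"]
    if chunks:
        out = pd.concat(chunks, ignore_index=True)[cols]
    else:
        out = pd.DataFrame(columns=cols)
    if report is not None:
        report.add("alignment", len(hr_logs), len(out), skipped_windows=n_skipped)
    return out


def filter_hr_percentiles(records: pd.DataFrame,
                          config: PreprocessConfig | None = None,
                          report: FiltrationReport | None = None) -> pd.DataFrame:
    """Drop records in the tails of the pooled heart-rate distribution.

    Percentiles are computed once on the pooled records across all
    participants with the linear-interpolation quantile definition;
    records strictly below the lower or strictly above the upper
    percentile are removed.  Note the filter is only idempotent if the
    percentiles are *not* recomputed on its own output.
    """
    config = config or PreprocessConfig()
    config.validate()
    if len(records) == 0:
        raise ValueError("cannot compute percentiles of an empty record set")
    if len(records) < 20:
        import warnings

        warnings.warn("fewer than 20 records; HR percentiles are degenerate")
    hr = records["hr"].to_numpy(float)
    lo, hi = np.percentile(hr, [config.hr_lower_percentile, config.hr_upper_percentile])
    out = records.loc[(hr >= lo) & (hr <= hi)].copy()
    if report is not None:
        report.add("hr_percentile_filter", len(records), len(out),
                   hr_lower=float(lo), hr_upper=float(hi))
    return out


def filter_min_records(records: pd.DataFrame,
                       config: PreprocessConfig | None = None,
                       report: FiltrationReport | None = None) -> pd.DataFrame:
    """Drop participants contributing fewer than the minimum record count.

    A participant with exactly ``min_records_per_participant`` records is
    kept.
    """
    config = config or PreprocessConfig()
    config.validate()
    counts = records.groupby("participant_id")["hr"].size()
    keep = counts.index[counts >= config.min_records_per_participant]
    out = records.loc[records["participant_id"].isin(keep)].copy()
    if report is not None:
        report.add("min_records_filter", len(records), len(out),
                   participants_in=int(counts.size), participants_out=int(len(keep)))
    return out


def effective_sampling_frequency(records: pd.DataFrame,
                                 config: PreprocessConfig | None = None) -> dict:
    """Records per hour of the day, per participant-day.

    Counts records in each observed (participant, date, hour) cell and
    aggregates to per-hour means/s.d. across cells and a grand mean.
    Hours in which a participant-day has no records do not form cells
    (device not worn), so the figure describes the sampling density of
    *logged* hours.
    """
    config = config or PreprocessConfig()
    cells = (records.groupby(["participant_id", "date", "hour"])
             .size().rename("n").reset_index())
    per_hour = cells.groupby("hour")["n"].agg(["mean", "std", "count"])
    return {
        "grand_mean": float(cells["n"].mean()) if len(cells) else float("nan"),
        "grand_sd": float(cells["n"].std(ddof=1)) if len(cells) > 1 else float("nan"),
        "per_hour": per_hour.reset_index().to_dict(orient="records"),
        "n_participant_days": int(cells.groupby(["participant_id", "date"]).ngroups),
    }


def haversine_distance(lat1, lon1, lat2, lon2, r: float = 6_371_000.0):
    """Great-circle distance in metres between two WGS-style coordinates.

    ``d = 2 r arcsin( sqrt( sin^2(dphi/2) + cos(phi1) cos(phi2)
    sin^2(dlambda/2) ) )`` with angles in radians.  Symmetric,
    non-negative and bounded by ``pi * r``.  Inputs are degrees; accepts
    scalars or arrays.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(a, dtype=float) for a in (lat1, lon1, lat2, lon2))
    if np.any(np.abs(lat1) > 90) or np.any(np.abs(lat2) > 90):
        raise ValueError("latitude must be within [-90, 90] degrees")
    if np.any(np.abs(lon1) > 180) or np.any(np.abs(lon2) > 180):
        raise ValueError("longitude must be within [-180, 180] degrees")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * r * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def movement_speed(gps_logs: pd.DataFrame, records: pd.DataFrame,
                   config: PreprocessConfig | None = None,
                   report: FiltrationReport | None = None) -> pd.DataFrame:
    """Attach 5-min mean movement speed and decile labels to records.

    Per participant, consecutive GPS fixes give step speeds ``d / dt``
    (haversine distance over the elapsed time; steps with ``dt <= 0`` are
    skipped).  Each record's ``movement`` is the mean of the step speeds
    whose end time falls in the half-open window ``(t - window, t]``.
    Records whose *window mean* exceeds ``max_speed`` are excluded — a
    single fast step inside an otherwise slow window does not exclude the
    record.  Decile labels (1-10, ties to the lower bin) come from the
    pooled retained movement values.

    Records without any GPS step in the window are returned with
    ``movement`` NaN; the movement-bearing subset is the complement.
    """
    config = config or PreprocessConfig()
    config.validate()
    out = records.copy()
    out["movement"] = np.nan

    for pid, g in gps_logs.groupby("participant_id"):
        g = g.copy()
        g["__ts"] = _parse_timestamps(g)
        g = g.sort_values("__ts")
        ts = g["__ts"].to_numpy(dtype="datetime64[ns]")
        lat = g["latitude"].to_numpy(float)
        lon = g["longitude"].to_numpy(float)
        if len(g) < 2:
            continue
        dt = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s")
        ok = dt > 0
        d = haversine_distance(lat[:-1], lon[:-1], lat[1:], lon[1:], config.earth_radius)
        step_speed = np.where(ok, d / np.where(ok, dt, 1.0), np.nan)[ok]
        step_end = ts[1:][ok]

        mask = out["participant_id"] == pid
        if not mask.any():
            continue
        rt = pd.to_datetime(out.loc[mask, "timestamp"]).to_numpy(dtype="datetime64[ns]")
        t0 = rt - np.timedelta64(int(config.window_seconds * 1e9), "ns")
        lo = np.searchsorted(step_end, t0, side="right")
        hi = np.searchsorted(step_end, rt, side="right")
        csum = np.concatenate([[0.0], np.cumsum(step_speed)])
        n = hi - lo
        with np.errstate(invalid="ignore"):
            mv = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
        out.loc[mask, "movement"] = mv

    n_with = int(out["movement"].notna().sum())
    keep = ~(out["movement"] > config.max_speed)   # NaN-safe: NaN compares False
    n_fast = int((~keep).sum())
    out = out.loc[keep].copy()

    mv = out["movement"].to_numpy(float)
    has = np.isfinite(mv)
    out["movement_decile"] = pd.array([pd.NA] * len(out), dtype="Int64")
    if has.sum() >= config.n_movement_bins:
        qs = np.quantile(mv[has], np.linspace(0, 1, config.n_movement_bins + 1)[1:-1])
        labels = 1 + np.searchsorted(qs, mv[has], side="left")
        col = out["movement_decile"].copy()
        col[has] = labels
        out["movement_decile"] = col
    if report is not None:
        report.add("movement_filter", len(records), len(out),
                   records_with_movement=n_with, excluded_fast=n_fast)
    return out


def build_records(hr_logs: pd.DataFrame, sound_logs: pd.DataFrame,
                  gps_logs: pd.DataFrame | None = None,
                  config: PreprocessConfig | None = None,
                  hr_percentile_filter: bool = True) -> tuple[pd.DataFrame, FiltrationReport]:
    """Full preprocessing pipeline in the fixed stage order.

    daytime filter (both log types) -> window alignment -> pooled HR
    percentile filter -> minimum-records participant filter -> optional
    movement attachment.  Returns the analysis records and the
    stage-by-stage filtration report.

    ``hr_percentile_filter=False`` skips the pooled tail filter and yields
    the plain aligned record set.  Because that filter selects on the
    response, samples passed through it no longer follow a generative
    linear model exactly; parameter-recovery studies therefore fit on the
    aligned records.
    """
    config = config or PreprocessConfig()
    config.validate()
    report = FiltrationReport()
    snd = filter_daytime(sound_logs, config, report)
    hr = filter_daytime(hr_logs, config, report)
    rec = align_records(hr, snd, config, report)
    if len(rec) == 0:
        return rec, report
    if hr_percentile_filter:
        rec = filter_hr_percentiles(rec, config, report)
    rec = filter_min_records(rec, config, report)
    if gps_logs is not None and len(gps_logs):
        rec = movement_speed(gps_logs, rec, config, report)
    return rec, report
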