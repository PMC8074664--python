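"""Filtration, alignment, movement and haversine tests on toy fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hearbeat.config import PreprocessConfig
from hearbeat.preprocess import (
    FiltrationReport,
    align_records,
    build_records,
    effective_sampling_frequency,
    filter_daytime,
    filter_hr_percentiles,
    filter_min_records,
    haversine_distance,
    movement_speed,
)

R_EARTH = 6_371_000.0


def _hr(ts_list, pid="P00", hr=75.0):
    return pd.DataFrame({"participant_id": pid, "timestamp": pd.to_datetime(ts_list),
                         "hr": hr})


def _snd(ts_list, pid="P00", spl=60.0, sml=15.0, snr=5.0, cls="Quiet"):
    n = len(ts_list)
    return pd.DataFrame({"participant_id": pid, "timestamp": pd.to_datetime(ts_list),
                         "spl": np.broadcast_to(spl, n).astype(float),
                         "sml": np.broadcast_to(sml, n).astype(float),
                         "snr": np.broadcast_to(snr, n).astype(float),
                         "soundscape": cls})


class TestDaytimeFilter:
    def test_0600_boundary_convention(self):
        logs = _hr(["2019-06-03 05:59:59", "2019-06-03 06:00:00",
                    "2019-06-03 23:59:59"])
        out = filter_daytime(logs)
        kept = pd.to_datetime(out["timestamp"]).dt.strftime("%H:%M:%S").tolist()
        assert kept == ["06:00:00", "23:59:59"]

    def test_empty_input(self):
        assert len(filter_daytime(_hr([]))) == 0

    def test_toy_counts(self):
        times = [f"2019-06-03 {h:02d}:30:00" for h in (1, 3, 5, 7, 9, 11, 13, 15, 17, 19)]
        assert len(filter_daytime(_hr(times))) == 7

    def test_unparseable_timestamp_names_row(self):
        logs = pd.DataFrame({"participant_id": ["P00"], "timestamp": ["not-a-time"],
                             "hr": [75.0]})
        with pytest.raises(ValueError, match="rows \\[0\\]"):
            filter_daytime(logs)


class TestAlignment:
    def test_window_mean_of_five_logs(self):
        t = pd.Timestamp("2019-06-03 10:00:00")
        snd = _snd([t - pd.Timedelta(seconds=s) for s in (240, 180, 120, 60, 0)],
                   spl=[50, 51, 52, 53, 54])
        rec = align_records(_hr([t]), snd)
        assert len(rec) == 1
        assert rec.loc[0, "spl"] == pytest.approx(52.0)
        assert rec.loc[0, "n_window_logs"] == 5

    def test_too_few_window_logs_skips_record(self):
        t = pd.Timestamp("2019-06-03 10:00:00")
        snd = _snd([t - pd.Timedelta(seconds=60), t])
        report = FiltrationReport()
        rec = align_records(_hr([t]), snd, report=report)
        assert len(rec) == 0
        assert report.stages[0]["skipped_windows"] == 1

    def test_window_is_half_open(self):
        # a log exactly at t-300 is excluded, one exactly at t is included
        t = pd.Timestamp("2019-06-03 10:00:00")
        snd = _snd([t - pd.Timedelta(seconds=300), t - pd.Timedelta(seconds=200),
                    t - pd.Timedelta(seconds=100), t], spl=[999.0, 50.0, 52.0, 54.0])
        rec = align_records(_hr([t]), snd)
        assert rec.loc[0, "n_window_logs"] == 3
        assert rec.loc[0, "spl"] == pytest.approx(52.0)

    def test_modal_class_with_complexity_tiebreak(self):
        t = pd.Timestamp("2019-06-03 10:00:00")
        snd = _snd([t - pd.Timedelta(seconds=s) for s in (240, 180, 120, 60)])
        snd["soundscape"] = ["Quiet", "Quiet", "Speech", "Speech"]
        rec = align_records(_hr([t]), snd)
        assert rec.loc[0, "soundscape"] == "Speech"


class TestPercentileFilter:
    def test_100_distinct_values_keep_90(self):
        # brute-force oracle under the linear-interpolation quantile definition
        hrs = np.arange(100, dtype=float) + 50.0
        rec = pd.DataFrame({"participant_id": "P00", "hr": hrs})
        lo = np.percentile(hrs, 5)
        hi = np.percentile(hrs, 95)
        expected = int(((hrs >= lo) & (hrs <= hi)).sum())
        out = filter_hr_percentiles(rec)
        assert len(out) == expected == 90

    def test_identical_values_remove_nothing(self):
        rec = pd.DataFrame({"participant_id": "P00", "hr": np.full(50, 75.0)})
        assert len(filter_hr_percentiles(rec)) == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            filter_hr_percentiles(pd.DataFrame({"participant_id": [], "hr": []}))


class TestMinRecordsFilter:
    def test_boundary_at_exactly_50(self):
        rec = pd.concat([
            pd.DataFrame({"participant_id": "A", "hr": np.ones(49)}),
            pd.DataFrame({"participant_id": "B", "hr": np.ones(50)}),
        ])
        out = filter_min_records(rec)
        assert set(out["participant_id"]) == {"B"}

    def test_toy_cohort_counts(self):
        rec = pd.concat([
            pd.DataFrame({"participant_id": "A", "hr": np.ones(60)}),
            pd.DataFrame({"participant_id": "B", "hr": np.ones(50)}),
            pd.DataFrame({"participant_id": "C", "hr": np.ones(10)}),
        ])
        out = filter_min_records(rec)
        assert len(out) == 110
        assert out["participant_id"].nunique() == 2


class TestEffectiveSampling:
    def test_one_record_per_hour_gives_unit_mean_zero_sd(self):
        rows = [{"participant_id": p, "date": "2019-06-03", "hour": h, "hr": 75}
                for p in ("A", "B") for h in range(6, 24)]
        esf = effective_sampling_frequency(pd.DataFrame(rows))
        assert esf["grand_mean"] == pytest.approx(1.0)
        assert esf["grand_sd"] == pytest.approx(0.0)

    def test_peak_hour_detected(self):
        rows = [{"participant_id": "A", "date": "2019-06-03", "hour": h, "hr": 75}
                for h in range(6, 24)]
        rows += [{"participant_id": "A", "date": "2019-06-03", "hour": 19, "hr": 75}]
        esf = effective_sampling_frequency(pd.DataFrame(rows))
        per_hour = {d["hour"]: d["mean"] for d in esf["per_hour"]}
        assert per_hour[19] == max(per_hour.values()) == 2.0


class TestHaversine:
    def test_identical_points_zero(self):
        assert haversine_distance(55.7, 12.5, 55.7, 12.5) == 0.0

    def test_antipodal_equator_is_pi_r(self):
        assert haversine_distance(0.0, 0.0, 0.0, 180.0) == \
            pytest.approx(np.pi * R_EARTH, rel=1e-12)

    def test_equator_to_pole_is_half_pi_r(self):
        assert haversine_distance(0.0, 0.0, 90.0, 0.0) == \
            pytest.approx(np.pi * R_EARTH / 2, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-90, 90), st.floats(-180, 180),
           st.floats(-90, 90), st.floats(-180, 180))
    def test_symmetric_nonnegative_bounded(self, lat1, lon1, lat2, lon2):
        d12 = haversine_distance(lat1, lon1, lat2, lon2)
        d21 = haversine_distance(lat2, lon2, lat1, lon1)
        assert d12 == pytest.approx(d21, abs=1e-6)
        assert 0.0 <= d12 <= np.pi * R_EARTH + 1e-6

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(ValueError):
            haversine_distance(95.0, 0.0, 0.0, 0.0)


def _gps_track(step_m, pid="P00", n=12, t0="2019-06-03 10:00:00"):
    """North-going track with given metre steps per minute."""
    lat = 55.0 + np.cumsum([0.0] + [s / R_EARTH * 180 / np.pi for s in step_m[:n - 1]])
    ts = pd.date_range(t0, periods=n, freq="60s")
    return pd.DataFrame({"participant_id": pid, "timestamp": ts,
                         "latitude": lat, "longitude": 12.5})


class TestMovement:
    def _records_at(self, t, pid="P00"):
        return pd.DataFrame({"participant_id": pid, "timestamp": [pd.Timestamp(t)],
                             "hr": [75.0]})

    def test_stationary_track_zero_movement(self):
        gps = _gps_track([0.0] * 11)
        rec = movement_speed(gps, self._records_at("2019-06-03 10:11:00"))
        assert rec["movement"].iloc[0] == pytest.approx(0.0)

    def test_constant_steps_give_two_mps(self):
        gps = _gps_track([120.0] * 11)
        rec = movement_speed(gps, self._records_at("2019-06-03 10:11:00"))
        assert rec["movement"].iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_single_fast_step_does_not_exclude_slow_window(self):
        # one 660 m minute (11 m/s) among slow steps: window mean decides
        steps = [30.0, 30.0, 660.0, 30.0, 30.0] + [30.0] * 6
        gps = _gps_track(steps)
        rec = movement_speed(gps, self._records_at("2019-06-03 10:05:00"))
        assert len(rec) == 1
        assert rec["movement"].iloc[0] == pytest.approx((30 * 4 + 660) / 5 / 60, rel=1e-6)

    def test_window_mean_above_threshold_excludes_record(self):
        gps = _gps_track([700.0] * 11)   # 11.7 m/s sustained
        rec = movement_speed(gps, self._records_at("2019-06-03 10:11:00"))
        assert len(rec) == 0

    def test_decile_labels_from_pooled_values(self):
        base = pd.Timestamp("2019-06-03 10:11:00")
        recs = pd.DataFrame({
            "participant_id": "P00",
            "timestamp": [base + pd.Timedelta(minutes=11 * k) for k in range(12)],
            "hr": 75.0})
        steps = np.repeat(np.arange(12) * 12.0, 11)
        gps = _gps_track(list(steps), n=len(steps) + 1)
        out = movement_speed(gps, recs)
        labels = out["movement_decile"].dropna().astype(int)
        assert labels.min() == 1 and labels.max() == 10
        assert out.sort_values("movement")["movement_decile"].is_monotonic_increasing


class TestFullPipeline:
    def test_stagewise_count_conservation(self, small_cohort, small_records):
        rec, report = small_records
        for stage in report.to_dict()["stages"]:
            assert stage["in"] == stage["out"] + stage["dropped"]
        align = [s for s in report.stages if s["stage"] == "alignment"][0]
        assert align["dropped"] == align["skipped_windows"]

    def test_filters_are_pure(self, small_cohort):
        a, _ = build_records(small_cohort.hr_logs, small_cohort.sound_logs)
        b, _ = build_records(small_cohort.hr_logs, small_cohort.sound_logs)
        pd.testing.assert_frame_equal(a, b)

    def test_records_have_daytime_hours_and_min_window(self, small_records):
        rec, _ = small_records
        assert rec["hour"].between(6, 23).all()
        assert (rec["n_window_logs"] >= 3).all()
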