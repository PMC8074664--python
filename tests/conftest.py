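"""Shared fixtures: small simulated cohorts and hand-built toy tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hearbeat.config import ModelSpec
from hearbeat.preprocess import build_records
from hearbeat.synthetic import scenario_config, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but structurally complete cohort (8 participants x 4 days)."""
    cfg = scenario_config("acoustic", n_participants=8, n_days=4, seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    rec, report = build_records(small_cohort.hr_logs, small_cohort.sound_logs,
                                small_cohort.gps_logs)
    return rec, report


def make_records(n_participants=6, n_per=80, beta=None, sd_intercept=0.0,
                 sd_resid=1.0, phi=0.0, seed=0, hour_spread=True):
    """Hand-rolled analysis records following a known linear model.

    ``hr = 70 + beta . z(spl, sml, snr) + b0_p + AR(1) noise`` with
    standard-normal acoustic columns; small and fast, for model unit tests.
    """
    beta = np.zeros(3) if beta is None else np.asarray(beta, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    base = pd.Timestamp("2019-06-03 08:00:00")
    for p in range(n_participants):
        b0 = rng.normal(0, sd_intercept)
        x = rng.normal(0, 1, size=(n_per, 3))
        e = np.empty(n_per)
        e[0] = rng.normal(0, sd_resid)
        for i in range(1, n_per):
            e[i] = phi * e[i - 1] + np.sqrt(max(1 - phi * phi, 1e-12)) * \
                rng.normal(0, sd_resid)
        y = 70.0 + x @ beta + b0 + e
        for i in range(n_per):
            ts = base + pd.Timedelta(minutes=8 * i)
            rows.append({
                "participant_id": f"P{p:02d}", "timestamp": ts, "hr": y[i],
                "spl": x[i, 0], "sml": x[i, 1], "snr": x[i, 2],
                "soundscape": ["Quiet", "Speech", "SpeechInNoise", "Noise"][i % 4],
                "n_window_logs": 5, "date": ts.date().isoformat(),
                "weekday": int(ts.weekday()),
                "hour": int(ts.hour) if hour_spread else 10,
                "movement": float(abs(x[i, 0])),
            })
    return pd.DataFrame(rows)


@pytest.fixture
def toy_records():
    return make_records()


def basic_spec(**kw) -> ModelSpec:
    """Random-intercept-only AR(1) spec used by several model tests."""
    defaults = dict(fixed="movement", predictor_scaling="raw_db",
                    random_slopes=False, weekday_level=False, hour_level=False)
    defaults.update(kw)
    return ModelSpec(**defaults)
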