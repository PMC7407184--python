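import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from somnipy import (
    DayWindow,
    SensorRecord,
    SimConfig,
    SleepReport,
    clean_discontinuities,
    simulate_week,
)

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_record(n=100, period=30.0, start="2020-07-06T12:00:00",
                motion=None, light=None, hr=None):
    """Small helper: build a regular SensorRecord from channel arrays."""
    idx = pd.Timestamp(start) + pd.to_timedelta(
        np.arange(n) * period, unit="s")
    df = pd.DataFrame(
        {
            "motion": np.zeros(n) if motion is None else np.asarray(motion, float),
            "light": np.zeros(n) if light is None else np.asarray(light, float),
            "hr": np.full(n, np.nan) if hr is None else np.asarray(hr, float),
        },
        index=pd.DatetimeIndex(idx, name="timestamp"),
    )
    return SensorRecord(df, nominal_period=period)


def make_report(totals_min, start="2020-07-06T12:00:00"):
    """A SleepReport scaffold carrying given per-window sleep totals."""
    t0 = pd.Timestamp(start)
    rows = []
    for i, total in enumerate(totals_min):
        w = DayWindow(
            start=t0 + pd.Timedelta(days=i),
            end=t0 + pd.Timedelta(days=i + 1),
            samples=pd.DataFrame(),
        )
        rows.append((w, [], float(total)))
    return SleepReport(windows=rows)


@pytest.fixture(scope="session")
def default_week():
    """One simulated default-condition week, cleaned, with its truth."""
    record, truth = simulate_week(SimConfig(seed=7))
    cleaned, _ = clean_discontinuities(record)
    return cleaned, truth
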