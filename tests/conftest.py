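import datetime as dt

import numpy as np
import pandas as pd
import pytest

from skyflux.regularize import SLOTS_PER_DAY, RegularSeries, sampling_days
from skyflux.series import HEIGHTS_M, N_BINS, Station
from skyflux.simulate import SimulationConfig, simulate_profile_series


@pytest.fixture(scope="session")
def ktlx() -> Station:
    return Station("KTLX", 35.333, -97.278, 370.0)


@pytest.fixture(scope="session")
def ten_day_config():
    return SimulationConfig(start_date=dt.date(2022, 4, 1), end_date=dt.date(2022, 4, 10), seed=42)


@pytest.fixture(scope="session")
def ten_day_series(ten_day_config):
    """One simulated 10-day series shared across tests (read-only)."""
    return simulate_profile_series(ten_day_config)


def make_regular_series(day_passage, station=None):
    """Hand-built RegularSeries with prescribed (diurnal, nocturnal) passage.

    ``day_passage`` is a list of (diurnal_total, nocturnal_total); each
    sampling day gets its passage in two single slots, the rest zeros.
    Returns (RegularSeries, diel_context) where the context labels the
    first half of each sampling day diurnal and the second nocturnal.
    """
    station = station or Station("TEST", 40.0, -100.0)
    n_days = len(day_passage)
    start = pd.Timestamp("2022-04-01 20:00")
    idx = pd.date_range(start, periods=n_days * SLOTS_PER_DAY, freq="5min")
    total = np.zeros(len(idx))
    phase = np.empty(len(idx), dtype=object)
    for d, (diur, noct) in enumerate(day_passage):
        lo = d * SLOTS_PER_DAY
        phase[lo : lo + SLOTS_PER_DAY // 2] = "diurnal"
        phase[lo + SLOTS_PER_DAY // 2 : lo + SLOTS_PER_DAY] = "nocturnal"
        total[lo] = diur
        total[lo + SLOTS_PER_DAY // 2] = noct
    slots = pd.DataFrame(
        {
            "total_rtr": total,
            "rain_fraction": 0.0,
            "gap_minutes": 0.0,
            "source_scan_time": idx,
            "rain_excluded": False,
            "valid": True,
            "sampling_day": (idx - pd.Timedelta(hours=20)).floor("D"),
        },
        index=idx,
    )
    rtr_bins = np.zeros((len(idx), N_BINS))
    rtr_bins[:, 5] = total  # all passage at 500-600 m
    reg = RegularSeries(station, slots, rtr_bins)
    reg.day_summary = sampling_days(reg)
    ctx = pd.DataFrame(
        {
            "solar_elevation": np.where(phase == "diurnal", 30.0, -30.0),
            "phase": phase,
            "hours_after_sunset": np.tile(
                np.r_[np.linspace(12, 23.9, SLOTS_PER_DAY // 2),
                      np.linspace(0, 11.9, SLOTS_PER_DAY // 2)],
                n_days,
            ),
            "season": "spring",
        },
        index=idx,
    )
    return reg, ctx
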