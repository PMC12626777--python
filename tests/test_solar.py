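"""Solar geometry against an independent astronomical-almanac oracle."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from skyflux import solar


def almanac_elevation(lat, lon, when):
    """Independent oracle: Michalsky's Astronomical Almanac algorithm
    (valid 1950-2050), a different formulation from the NOAA equations
    used by the implementation."""
    ts = pd.Timestamp(when)
    jd = ts.to_julian_date()
    n = jd - 2451545.0
    L = (280.460 + 0.9856474 * n) % 360.0
    g = np.deg2rad((357.528 + 0.9856003 * n) % 360.0)
    lam = np.deg2rad(L + 1.915 * np.sin(g) + 0.020 * np.sin(2 * g))
    eps = np.deg2rad(23.439 - 0.0000004 * n)
    delta = np.arcsin(np.sin(eps) * np.sin(lam))
    ra = np.arctan2(np.cos(eps) * np.sin(lam), np.cos(lam))
    ut_hours = ts.hour + ts.minute / 60 + ts.second / 3600 + ts.microsecond / 3.6e9
    gmst = (6.697375 + 0.0657098242 * (jd - 2451545.0 - ut_hours / 24.0) + 1.00273790935 * ut_hours) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = np.deg2rad(lmst * 15.0) - ra
    lat_r = np.deg2rad(lat)
    sin_el = np.sin(lat_r) * np.sin(delta) + np.cos(lat_r) * np.cos(delta) * np.cos(ha)
    return np.rad2deg(np.arcsin(np.clip(sin_el, -1, 1)))


@pytest.mark.parametrize(
    "lat,lon,when",
    [
        (35.333, -97.278, "2022-04-15 18:00"),
        (35.333, -97.278, "2022-04-16 02:30"),
        (45.0, 7.0, "2010-09-21 12:00"),
        (-33.9, 151.2, "2018-01-05 02:00"),
        (64.8, -147.7, "2001-06-21 22:00"),
        (0.0, 0.0, "2022-03-20 12:07"),
    ],
)
def test_elevation_matches_almanac_oracle(lat, lon, when):
    ours = solar.solar_elevation(lat, lon, when)
    theirs = almanac_elevation(lat, lon, when)
    assert abs(ours - theirs) < 0.2


def test_equator_equinox_noon_near_zenith():
    # local solar noon at the prime meridian on the March equinox
    elev = solar.solar_elevation(0.0, 0.0, "2022-03-20 12:07")
    assert elev > 88.0


def test_solar_midnight_depression_sign():
    # around local solar midnight the sun sits far below the horizon,
    # roughly -(90 - |lat| - |declination|) degrees
    elev = solar.solar_elevation(35.0, 0.0, "2022-03-21 00:00")
    assert elev < -45.0


def test_crossings_are_zero_elevation_and_ordered():
    sunset, sunrise = solar.sun_crossings(35.333, -97.278, dt.date(2022, 4, 15))
    for t in (sunset, sunrise):
        assert abs(solar.solar_elevation(35.333, -97.278, t)) < 0.01
    # at this longitude sunset falls near 01 UT and sunrise near 12 UT
    assert sunset.hour < 3 and 10 < sunrise.hour < 14


def test_equinox_daylength_near_12h():
    sunset, sunrise = solar.sun_crossings(0.0, 0.0, dt.date(2022, 3, 20))
    daylength = abs((sunset - sunrise) / pd.Timedelta(hours=1))
    daylength = min(daylength, 24 - daylength)
    assert abs(daylength - 12.0) < 5 / 60


def test_polar_day_flagged():
    with pytest.raises(solar.PolarNightError):
        solar.sun_crossings(80.0, 0.0, dt.date(2022, 6, 21))


def test_hours_after_sunset_continuous_and_small_after_sunset():
    lat, lon = 35.333, -97.278
    sunset, _ = solar.sun_crossings(lat, lon, dt.date(2022, 4, 15))
    just_after = sunset + pd.Timedelta(minutes=1)
    assert solar.hours_after_sunset(lat, lon, just_after) == pytest.approx(1 / 60, abs=1e-3)
    # continuity across the UTC-midnight boundary
    before = solar.hours_after_sunset(lat, lon, pd.Timestamp("2022-04-16 23:59"))
    after = solar.hours_after_sunset(lat, lon, pd.Timestamp("2022-04-17 00:01"))
    assert after - before == pytest.approx(2 / 60, abs=1e-3)


def test_phase_assignment_strict_boundary():
    lat, lon = 35.333, -97.278
    sunset, _ = solar.sun_crossings(lat, lon, dt.date(2022, 4, 15))
    ctx = solar.assign_phase(
        [sunset - pd.Timedelta(minutes=5), sunset + pd.Timedelta(minutes=5),
         pd.Timestamp("2022-04-15 18:00")],
        lat, lon,
    )
    assert list(ctx["phase"]) == ["diurnal", "nocturnal", "diurnal"]
    # nocturnal requires elevation strictly < 0
    assert (ctx.loc[ctx["phase"] == "nocturnal", "solar_elevation"] < 0).all()


def test_phase_partitions_every_slot(ten_day_series):
    series, _ = ten_day_series
    st = series.station
    times = pd.date_range("2022-04-02 20:00", periods=288, freq="5min")
    ctx = solar.assign_phase(times, st.latitude, st.longitude)
    assert set(ctx["phase"]) == {"diurnal", "nocturnal"}
    assert len(ctx) == 288


@pytest.mark.parametrize(
    "season,count", [("spring", 106), ("summer", 45), ("autumn", 106)]
)
def test_season_sampling_day_counts(season, count):
    # complete 20:00-19:59 UTC windows inside the inclusive calendar span
    for year in (2020, 2022):  # leap and common year
        assert solar.season_sampling_day_count(season, year) == count


def test_season_membership_and_disjointness():
    assert solar.season_of(dt.date(2022, 3, 1)) == "spring"
    assert solar.season_of(dt.date(2022, 6, 15)) == "spring"
    assert solar.season_of(dt.date(2022, 6, 16)) == "summer"
    assert solar.season_of(dt.date(2022, 8, 1)) == "autumn"
    assert solar.season_of(dt.date(2022, 11, 16)) == "none"
    assert solar.season_of(dt.date(2022, 1, 10)) == "none"
    # windows are disjoint: each date maps to exactly one season
    d = dt.date(2022, 1, 1)
    while d < dt.date(2023, 1, 1):
        n = sum(
            start <= (d.month, d.day) <= end
            for start, end in solar.SEASON_WINDOWS.values()
        )
        assert n <= 1
        d += dt.timedelta(days=1)
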