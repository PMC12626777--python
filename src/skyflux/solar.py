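"""Solar geometry: elevation angle, sunset/sunrise, diel phase, and seasons.

Implements the NOAA solar-position equations (declination, equation of
time, hour angle) for the geometric solar elevation angle — no
atmospheric refraction, so the horizon crossing is at a true solar
angle of 0 degrees.  The nocturnal phase is defined by a solar
elevation strictly below zero; sunset and sunrise are the downward and
upward zero crossings of the elevation angle.

All timestamps are UTC.  Naive ``datetime``/``Timestamp`` objects are
interpreted as UTC.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "solar_elevation",
    "sun_crossings",
    "most_recent_sunset",
    "hours_after_sunset",
    "assign_phase",
    "season_of",
    "season_window",
    "season_sampling_day_count",
    "PolarNightError",
    "DielContext",
]

_J2000 = pd.Timestamp("2000-01-01 12:00:00")

# Inclusive calendar windows (month, day) for the migratory seasons.
SEASON_WINDOWS = {
    "spring": ((3, 1), (6, 15)),
    "summer": ((6, 16), (7, 31)),
    "autumn": ((8, 1), (11, 15)),
}


class PolarNightError(ValueError):
    """The sun does not cross the horizon on the requested date."""


def _to_utc_naive(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts.tzinfo is not None:
        ts = ts.tz_convert("UTC").tz_localize(None)
    return ts


def _julian_century(times: np.ndarray) -> np.ndarray:
    """Julian centuries since J2000.0 for an array of datetime64[ns]."""
    delta = (times - _J2000.to_datetime64()) / np.timedelta64(1, "s")
    return delta / (86400.0 * 36525.0)


def solar_elevation(lat: float, lon: float, when) -> float | np.ndarray:
    """Geometric solar elevation angle in degrees.

    Parameters
    ----------
    lat, lon : float
        Site coordinates in degrees; longitude positive east.
    when : datetime-like or array of datetime64
        UTC instant(s).

    Returns
    -------
    float or ndarray
        Elevation of the solar centre above the geometric horizon,
        negative when the sun is below it.
    """
    if np.ndim(when) == 0:
        times = np.array([_to_utc_naive(when).to_datetime64()])
        scalar = True
    else:
        times = pd.DatetimeIndex(when).values
        scalar = False

    T = _julian_century(times)
    rad = np.deg2rad

    # Geometric mean longitude and anomaly of the sun (degrees)
    L0 = np.mod(280.46646 + T * (36000.76983 + 0.0003032 * T), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    e = 0.016708634 - T * (0.000042037 + 0.0000001267 * T)

    # Equation of centre -> true and apparent longitude
    C = (
        np.sin(rad(M)) * (1.914602 - T * (0.004817 + 0.000014 * T))
        + np.sin(rad(2 * M)) * (0.019993 - 0.000101 * T)
        + np.sin(rad(3 * M)) * 0.000289
    )
    true_long = L0 + C
    omega = 125.04 - 1934.136 * T
    app_long = true_long - 0.00569 - 0.00478 * np.sin(rad(omega))

    # Obliquity of the ecliptic (corrected) and solar declination
    eps0 = 23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - 0.001813 * T))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * np.cos(rad(omega))
    decl = np.arcsin(np.sin(rad(eps)) * np.sin(rad(app_long)))

    # Equation of time (minutes)
    y = np.tan(rad(eps / 2.0)) ** 2
    eot = 4.0 * np.rad2deg(
        y * np.sin(2 * rad(L0))
        - 2.0 * e * np.sin(rad(M))
        + 4.0 * e * y * np.sin(rad(M)) * np.cos(2 * rad(L0))
        - 0.5 * y * y * np.sin(4 * rad(L0))
        - 1.25 * e * e * np.sin(2 * rad(M))
    )

    # True solar time (minutes) -> hour angle (degrees)
    day_ns = (times - times.astype("datetime64[D]").astype("datetime64[ns]")).astype("int64")
    minutes_utc = day_ns / 60e9
    tst = np.mod(minutes_utc + eot + 4.0 * lon, 1440.0)
    ha = tst / 4.0 - 180.0

    sin_elev = np.sin(rad(lat)) * np.sin(decl) + np.cos(rad(lat)) * np.cos(decl) * np.cos(rad(ha))
    elev = np.rad2deg(np.arcsin(np.clip(sin_elev, -1.0, 1.0)))
    return float(elev[0]) if scalar else elev


@lru_cache(maxsize=4096)
def _crossings_cached(lat: float, lon: float, date_iso: str):
    date = dt.date.fromisoformat(date_iso)
    day_start = pd.Timestamp(date)
    # 5-min scan for sign changes, then bisection to <= 1 s.
    step = pd.Timedelta(minutes=5)
    grid = pd.date_range(day_start, day_start + pd.Timedelta(days=1), freq=step)
    elev = solar_elevation(lat, lon, grid)

    sunset = sunrise = None
    for i in range(len(grid) - 1):
        a, b = elev[i], elev[i + 1]
        if a == 0.0:  # grid point exactly on the horizon
            a = 1e-12 if b < 0 else -1e-12
        if (a > 0) != (b > 0):
            lo, hi = grid[i], grid[i + 1]
            for _ in range(64):
                mid = lo + (hi - lo) / 2
                if (solar_elevation(lat, lon, mid) > 0) == (a > 0):
                    lo = mid
                else:
                    hi = mid
                if hi - lo <= pd.Timedelta(seconds=1):
                    break
            t_cross = lo + (hi - lo) / 2
            if a > 0:  # downward crossing
                sunset = t_cross
            else:
                sunrise = t_cross
    return sunset, sunrise


def sun_crossings(lat: float, lon: float, date: dt.date) -> tuple[pd.Timestamp, pd.Timestamp]:
    """Sunset and sunrise (UTC) on a given UTC calendar date.

    Zero crossings of the geometric solar elevation, located by
    bisection to within one second.  Raises :class:`PolarNightError`
    when the sun stays on one side of the horizon all day (polar day
    or polar night), in which case sunset-referenced analyses must
    exclude the date.
    """
    sunset, sunrise = _crossings_cached(float(lat), float(lon), date.isoformat())
    if sunset is None or sunrise is None:
        raise PolarNightError(
            f"no horizon crossing at lat={lat}, lon={lon} on {date} (polar day/night)"
        )
    return sunset, sunrise


def most_recent_sunset(lat: float, lon: float, when) -> pd.Timestamp:
    """The last sunset at or before ``when`` (UTC)."""
    ts = _to_utc_naive(when)
    for back in range(3):
        date = (ts - pd.Timedelta(days=back)).date()
        try:
            sunset, _ = sun_crossings(lat, lon, date)
        except PolarNightError:
            continue
        if sunset <= ts:
            return sunset
    raise PolarNightError(f"no sunset within 3 days before {ts} at lat={lat}")


def hours_after_sunset(lat: float, lon: float, when) -> float:
    """Hours elapsed since the most recent sunset; continuous across midnight."""
    ts = _to_utc_naive(when)
    return (ts - most_recent_sunset(lat, lon, ts)) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class DielContext:
    """Solar context of one time slot."""

    timestamp: pd.Timestamp
    solar_elevation_deg: float
    phase: str  # 'diurnal' | 'nocturnal'
    hours_after_sunset: float
    season: str  # 'spring' | 'summer' | 'autumn' | 'none'


def assign_phase(times, lat: float, lon: float) -> pd.DataFrame:
    """Diel context for an array of UTC timestamps.

    Nocturnal requires a solar elevation strictly below zero; a slot
    exactly on the horizon is diurnal.  Returns a DataFrame indexed by
    timestamp with columns ``solar_elevation``, ``phase``,
    ``hours_after_sunset`` and ``season``.
    """
    idx = pd.DatetimeIndex(times)
    if idx.tz is not None:
        idx = idx.tz_convert("UTC").tz_localize(None)
    elev = solar_elevation(lat, lon, idx)
    phase = np.where(elev < 0.0, "nocturnal", "diurnal")
    has = np.array([hours_after_sunset(lat, lon, t) for t in idx])
    season = np.array([season_of(t.date()) for t in idx], dtype=object)
    return pd.DataFrame(
        {
            "solar_elevation": elev,
            "phase": phase,
            "hours_after_sunset": has,
            "season": season,
        },
        index=idx,
    )


def season_of(date: dt.date) -> str:
    """Season membership by inclusive calendar window.

    Spring: March 1 – June 15; summer: June 16 – July 31; autumn:
    August 1 – November 15; anything else is ``'none'``.  The windows
    contain no February, so membership is leap-year invariant.
    """
    key = (date.month, date.day)
    for name, (start, end) in SEASON_WINDOWS.items():
        if start <= key <= end:
            return name
    return "none"


def season_window(season: str, year: int) -> tuple[dt.date, dt.date]:
    """Inclusive first and last calendar date of a season in a year."""
    (m0, d0), (m1, d1) = SEASON_WINDOWS[season]
    return dt.date(year, m0, d0), dt.date(year, m1, d1)


def season_sampling_day_count(season: str, year: int) -> int:
    """Number of complete 20:00–19:59 UTC sampling windows in the season.

    A sampling day starting 20:00 UTC on date ``d`` ends 19:59 UTC on
    ``d + 1``; it is counted when both dates fall inside the inclusive
    seasonal window, giving one fewer than the calendar-day count
    (106 for spring, 45 for summer, 106 for autumn).
    """
    start, end = season_window(season, year)
    return (end - start).days
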