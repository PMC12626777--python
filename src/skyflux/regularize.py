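"""Temporal regularization and quality control.

Radar scans arrive irregularly (every ~4–10 min); analyses need a
regular 5-min grid.  Each grid slot takes the value of the
nearest-in-time scan when the gap is strictly under one hour,
otherwise it stays empty (linear interpolation between bracketing
scans is available behind a switch).  Slots whose scan had more than
25% of classified voxels labelled rain are excluded.  Time is then cut
into sampling days — 20:00 UTC to 19:59 UTC the next day, 288 slots —
and a day is retained only when at least 90% of its slots
(ceil(0.9 * 288) = 260) survive filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import HEIGHTS_M, N_BINS, ProfileSeries, Station

__all__ = ["RegularSeries", "regularize", "filter_rain", "sampling_days",
           "RAIN_MAX_FRACTION", "COMPLETENESS_MIN", "SLOTS_PER_DAY", "MIN_VALID_SLOTS"]

GRID_MINUTES = 5
SLOTS_PER_DAY = 288  # 24 h of 5-min slots
MAX_GAP_MINUTES = 60.0  # strict: gap must be < 60 min
RAIN_MAX_FRACTION = 0.25  # strict: excluded iff rain_fraction > 0.25
COMPLETENESS_MIN = 0.90
MIN_VALID_SLOTS = math.ceil(COMPLETENESS_MIN * SLOTS_PER_DAY)  # 260
DAY_START_HOUR_UTC = 20  # sampling day runs 20:00 -> 19:59 UTC


@dataclass
class RegularSeries:
    """A profile series resampled to the 5-min grid.

    ``slots`` is indexed by grid time with columns ``total_rtr``
    (NaN when empty), ``rain_fraction``, ``gap_minutes``,
    ``source_scan_time``, ``rain_excluded``, ``valid`` and
    ``sampling_day`` (the 20:00 UTC anchor date of the slot's window).
    ``rtr_bins`` holds the per-bin traffic-rate vectors, aligned with
    ``slots``; rows of empty slots are NaN.
    """

    station: Station
    slots: pd.DataFrame = field(repr=False)
    rtr_bins: np.ndarray = field(repr=False)
    day_summary: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def grid(self) -> pd.DatetimeIndex:
        return self.slots.index


def filter_rain(rain_fraction: float) -> bool:
    """True when the slot is kept: rain fraction not above 25%.

    The rule is strict — exactly 25% is kept, anything greater
    excluded.  A missing rain fraction counts as excluded (the slot is
    unusable without a contamination estimate).
    """
    if rain_fraction is None or not np.isfinite(rain_fraction):
        return False
    return rain_fraction <= RAIN_MAX_FRACTION


def _sampling_day_labels(times: pd.DatetimeIndex) -> np.ndarray:
    return (times - pd.Timedelta(hours=DAY_START_HOUR_UTC)).floor("D")


def regularize(series: ProfileSeries, method: str = "nearest") -> RegularSeries:
    """Resample a traffic-rate-bearing series to the 5-min grid.

    ``method='nearest'`` (default) assigns each slot the nearest scan
    within strictly less than 60 minutes; ``method='linear'``
    interpolates linearly between the bracketing scans when both are
    within the gap limit.  Scan times must be strictly increasing.
    """
    if "rtr_total" not in series.df.columns:
        raise ValueError("series lacks traffic rates; run add_traffic_rates first")
    if method not in ("nearest", "linear"):
        raise ValueError(f"unknown method {method!r}")
    scan_times = series.timestamps
    if not scan_times.is_monotonic_increasing or scan_times.has_duplicates:
        raise ValueError("scan timestamps must be strictly increasing and unique")

    scans = series.scan_table()  # rain_fraction, rtr_total per scan
    rtr_wide = series.bin_matrix("rtr_bin").reindex(columns=HEIGHTS_M).to_numpy()

    t0 = scan_times[0].floor(f"{GRID_MINUTES}min")
    t1 = scan_times[-1].ceil(f"{GRID_MINUTES}min")
    grid = pd.date_range(t0, t1, freq=f"{GRID_MINUTES}min")

    # nearest scan per slot via searchsorted on int64 nanoseconds
    sv = scan_times.asi8
    gv = grid.asi8
    right = np.searchsorted(sv, gv)
    left = np.clip(right - 1, 0, len(sv) - 1)
    right = np.clip(right, 0, len(sv) - 1)
    d_left = np.abs(gv - sv[left])
    d_right = np.abs(sv[right] - gv)
    nearest = np.where(d_right < d_left, right, left)  # ties favour the earlier scan
    gap_min = np.minimum(d_left, d_right) / 60e9
    filled = gap_min < MAX_GAP_MINUTES

    total = scans["rtr_total"].to_numpy()[nearest]
    rain = scans["rain_fraction"].to_numpy()[nearest]
    bins = rtr_wide[nearest, :]

    if method == "linear":
        gl = d_left / 60e9
        gr = (sv[right] - gv) / 60e9
        both = (gl < MAX_GAP_MINUTES) & (gr < MAX_GAP_MINUTES) & (right != left)
        w = np.zeros(len(grid))
        w[both] = gl[both] / (gl[both] + gr[both])
        tot_l, tot_r = scans["rtr_total"].to_numpy()[left], scans["rtr_total"].to_numpy()[right]
        total = np.where(both, (1 - w) * tot_l + w * tot_r, total)
        bins = np.where(
            both[:, None], (1 - w)[:, None] * rtr_wide[left, :] + w[:, None] * rtr_wide[right, :], bins
        )

    total = np.where(filled, total, np.nan)
    rain = np.where(filled, rain, np.nan)
    bins = np.where(filled[:, None], bins, np.nan)
    rain_excluded = filled & ~np.array([filter_rain(r) for r in rain])
    valid = filled & ~rain_excluded

    slots = pd.DataFrame(
        {
            "total_rtr": total,
            "rain_fraction": rain,
            "gap_minutes": gap_min,
            "source_scan_time": scan_times[nearest].where(filled),
            "rain_excluded": rain_excluded,
            "valid": valid,
            "sampling_day": _sampling_day_labels(grid),
        },
        index=grid,
    )
    reg = RegularSeries(series.station, slots, bins)
    reg.day_summary = sampling_days(reg)
    return reg


def sampling_days(reg: RegularSeries) -> pd.DataFrame:
    """Per-sampling-day QC table.

    A sampling day (20:00 UTC to 19:59 UTC next day) is *complete*
    when all 288 slots lie inside the series span, and *retained*
    when complete and at least 260 of them are valid after gap and
    rain filtering.
    """
    g = reg.slots.groupby("sampling_day")
    out = g.agg(
        n_slots=("valid", "size"),
        n_valid_slots=("valid", "sum"),
        n_rain_excluded=("rain_excluded", "sum"),
    )
    out["complete"] = out["n_slots"] == SLOTS_PER_DAY
    out["retained"] = out["complete"] & (out["n_valid_slots"] >= MIN_VALID_SLOTS)
    return out
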