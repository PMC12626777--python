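"""Core containers: radar station metadata and vertical-profile time series.

A :class:`ProfileSeries` is the package's central in-memory object: a
station plus a long-format :class:`pandas.DataFrame` with one row per
(scan timestamp, height bin).  Heights are the lower edges of 30
contiguous 100-m bins covering 0–3000 m above ground level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Station", "ProfileSeries", "N_BINS", "BIN_SIZE_M", "HEIGHTS_M", "PROFILE_COLUMNS"]

N_BINS = 30
BIN_SIZE_M = 100.0
#: Lower edges of the height bins, m AGL; bins are half-open [lo, lo + 100).
HEIGHTS_M = np.arange(N_BINS) * BIN_SIZE_M

#: Required columns of the long-format profile table.
PROFILE_COLUMNS = [
    "datetime",
    "height",
    "eta",
    "u",
    "v",
    "ground_speed",
    "direction",
    "n_voxels",
    "rain_fraction",
]


@dataclass(frozen=True)
class Station:
    """A radar site: name and geographic position."""

    name: str
    latitude: float
    longitude: float
    altitude_m: float = 0.0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude} outside [-180, 180]")


@dataclass
class ProfileSeries:
    """Time-ordered vertical profiles for one station.

    ``df`` holds one row per (datetime, height) with the columns in
    :data:`PROFILE_COLUMNS`; ``eta`` is linear reflectivity in
    cm^2 km^-3, winds in m/s, ``rain_fraction`` the scan-level fraction
    of classified voxels labelled rain.  Extra columns (e.g. traffic
    rates) are carried along untouched.
    """

    station: Station
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in PROFILE_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"profile table missing columns: {missing}")
        self.df = self.df.copy()
        self.df["datetime"] = pd.to_datetime(self.df["datetime"]).astype("datetime64[ns]")
        self.df = self.df.sort_values(["datetime", "height"], kind="stable").reset_index(drop=True)
        counts = self.df.groupby("datetime", sort=False).size()
        bad = counts[counts != N_BINS]
        if len(bad):
            raise ValueError(
                f"every timestamp needs exactly {N_BINS} height bins; "
                f"offending timestamps: {list(bad.index[:3])}"
            )

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.df["datetime"].unique())

    def __len__(self) -> int:
        return len(self.df) // N_BINS

    def scan_table(self) -> pd.DataFrame:
        """One row per scan: rain fraction plus any scan-level columns."""
        agg = {"rain_fraction": "first"}
        if "rtr_total" in self.df.columns:
            agg["rtr_total"] = "first"
        return self.df.groupby("datetime").agg(agg)

    def bin_matrix(self, column: str) -> pd.DataFrame:
        """Pivot one per-bin column to a (scan x 30 heights) wide table."""
        return self.df.pivot(index="datetime", columns="height", values=column)
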