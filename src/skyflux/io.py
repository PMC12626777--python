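"""Reading and writing vertical-profile time series (VPTS-style CSV).

The on-disk format is a plain CSV with one row per (datetime, height
bin) and a small commented header carrying station metadata:

    # radar: KTLX
    # latitude: 35.333
    # longitude: -97.278
    # altitude_m: 370.0
    radar,datetime,height,eta,u,v,ground_speed,direction,n_voxels,rain_fraction[,...]

``datetime`` is ISO-8601 UTC; ``height`` the lower bin edge in meters
AGL.  Unknown extra columns round-trip unchanged.  Polar-volume
fixtures use a similar plain columnar text format, one row per voxel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .profiles import PolarVolume, Sweep, VoxelClass
from .series import N_BINS, PROFILE_COLUMNS, ProfileSeries, Station

__all__ = ["read_vpts", "write_vpts", "read_polar_volume", "write_polar_volume"]


def write_vpts(series: ProfileSeries, path) -> None:
    """Write a profile series to VPTS-style CSV."""
    path = Path(path)
    st = series.station
    df = series.df.copy()
    df.insert(0, "radar", st.name)
    df["datetime"] = pd.DatetimeIndex(df["datetime"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    with open(path, "w") as fh:
        fh.write(f"# radar: {st.name}\n")
        fh.write(f"# latitude: {st.latitude}\n")
        fh.write(f"# longitude: {st.longitude}\n")
        fh.write(f"# altitude_m: {st.altitude_m}\n")
        df.to_csv(fh, index=False)


def read_vpts(path) -> ProfileSeries:
    """Read a VPTS-style CSV, validating schema and time ordering.

    Rejects files with a malformed header, timestamps out of order,
    or any timestamp that does not carry exactly 30 height bins — the
    diagnostics name the offending line or timestamp.
    """
    path = Path(path)
    meta = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            try:
                key, value = line[1:].split(":", 1)
            except ValueError as err:
                raise ValueError(f"{path}:{n_header}: malformed header line {line!r}") from err
            meta[key.strip()] = value.strip()
    for key in ("radar", "latitude", "longitude"):
        if key not in meta:
            raise ValueError(f"{path}: header missing '# {key}:' line")
    station = Station(
        meta["radar"], float(meta["latitude"]), float(meta["longitude"]),
        float(meta.get("altitude_m", 0.0)),
    )

    df = pd.read_csv(path, comment="#")
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["datetime"] = pd.to_datetime(df["datetime"], utc=True).dt.tz_localize(None)
    df = df.drop(columns=["radar"], errors="ignore")

    times = df["datetime"].to_numpy()
    change = np.flatnonzero(np.diff(times.astype("int64")) < 0)
    if change.size:
        row = int(change[0]) + 2 + n_header  # 1-based, after header + column line
        raise ValueError(f"{path}:{row}: timestamps out of order")
    counts = df.groupby("datetime", sort=False).size()
    bad = counts[counts != N_BINS]
    if len(bad):
        raise ValueError(
            f"{path}: timestamp {bad.index[0]} has {int(bad.iloc[0])} height bins, expected {N_BINS}"
        )
    return ProfileSeries(station, df)


_VOLUME_COLUMNS = ["sweep_elev", "azimuth", "range", "dbz", "vrad", "class"]
_CLASS_NAMES = {c.name.lower(): int(c) for c in VoxelClass}


def write_polar_volume(volume: PolarVolume, path) -> None:
    """Write a polar volume as plain columnar text, one row per voxel."""
    rows = []
    for sw in volume.sweeps:
        az2d, rng2d = np.meshgrid(sw.azimuth_deg, sw.range_km, indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "sweep_elev": sw.elevation_deg,
                    "azimuth": az2d.ravel(),
                    "range": rng2d.ravel(),
                    "dbz": sw.dbz.ravel(),
                    "vrad": sw.vrad.ravel(),
                    "class": [VoxelClass(c).name.lower() for c in sw.voxel_class.ravel()],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    st = volume.station
    with open(path, "w") as fh:
        fh.write(f"# radar: {st.name}\n")
        fh.write(f"# latitude: {st.latitude}\n")
        fh.write(f"# longitude: {st.longitude}\n")
        fh.write(f"# altitude_m: {st.altitude_m}\n")
        fh.write(f"# timestamp: {pd.Timestamp(volume.timestamp).isoformat()}Z\n")
        df.to_csv(fh, index=False)


def read_polar_volume(path) -> PolarVolume:
    """Read a columnar polar-volume fixture written by
    :func:`write_polar_volume`."""
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, value = line[1:].split(":", 1)
            meta[key.strip()] = value.strip()
    station = Station(
        meta["radar"], float(meta["latitude"]), float(meta["longitude"]),
        float(meta.get("altitude_m", 0.0)),
    )
    ts = pd.Timestamp(meta["timestamp"].rstrip("Z"))
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _VOLUME_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sweeps = []
    for elev, grp in df.groupby("sweep_elev", sort=True):
        az = np.sort(grp["azimuth"].unique())
        rng = np.sort(grp["range"].unique())
        pivot = grp.pivot(index="azimuth", columns="range")
        dbz = pivot["dbz"].reindex(index=az, columns=rng).to_numpy()
        vrad = pivot["vrad"].reindex(index=az, columns=rng).to_numpy()
        cls = (
            pivot["class"].reindex(index=az, columns=rng)
            .apply(lambda col: col.map(_CLASS_NAMES))
            .to_numpy()
        )
        sweeps.append(Sweep(float(elev), az, rng, dbz, vrad, cls.astype(np.int8)))
    return PolarVolume(station, ts, sweeps)
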