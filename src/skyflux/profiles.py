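"""From polar radar volumes to vertical profiles of biology.

Covers the radar-side primitives: 4/3-effective-Earth beam propagation,
conversion between reflectivity factor (dBZ) and linear reflectivity
eta (cm^2 km^-3), velocity-azimuth-display (VAD) wind retrieval, and
assembly of a 30-bin vertical profile (0–3000 m AGL, 100-m bins) from
the five lowest elevation sweeps restricted to 2.5–50 km range.

Precipitation/biology separation is an input here: every voxel carries
a class label (`biology`, `rain`, `clutter`, `missing`) produced
upstream, by a segmentation model on real data or by the simulator.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import BIN_SIZE_M, HEIGHTS_M, N_BINS, Station

__all__ = [
    "VoxelClass",
    "Sweep",
    "PolarVolume",
    "VerticalProfile",
    "ProfileOptions",
    "beam_height",
    "dbz_to_eta",
    "eta_to_dbz",
    "vad_fit",
    "build_profile",
]

#: Effective Earth radius for standard microwave refraction, meters.
K_A_M = (4.0 / 3.0) * 6_371_000.0

#: |K_m|^2 dielectric factor for liquid water, S-band convention.
KM2 = 0.93

#: Default radar wavelength, cm (S-band WSR-88D).
WAVELENGTH_CM = 10.71


class VoxelClass(enum.IntEnum):
    BIOLOGY = 0
    RAIN = 1
    CLUTTER = 2
    MISSING = 3


@dataclass
class Sweep:
    """One conical scan: a (rays x gates) grid of voxels."""

    elevation_deg: float
    azimuth_deg: np.ndarray  # (n_rays,)
    range_km: np.ndarray  # (n_gates,)
    dbz: np.ndarray  # (n_rays, n_gates); NaN = missing
    vrad: np.ndarray  # (n_rays, n_gates), m/s positive away; NaN = missing
    voxel_class: np.ndarray  # (n_rays, n_gates) of VoxelClass ints


@dataclass
class PolarVolume:
    """One radar acquisition: several sweeps at increasing elevation."""

    station: Station
    timestamp: pd.Timestamp
    sweeps: list[Sweep]

    def __post_init__(self):
        if not self.sweeps:
            raise ValueError("a polar volume needs at least one sweep")
        self.sweeps = sorted(self.sweeps, key=lambda s: s.elevation_deg)


@dataclass
class VerticalProfile:
    """One scan's 30-bin profile of biological reflectivity and wind."""

    timestamp: pd.Timestamp
    eta: np.ndarray  # cm^2 km^-3 per bin; NaN = missing
    u: np.ndarray
    v: np.ndarray
    ground_speed: np.ndarray
    direction: np.ndarray  # compass bearing toward movement, deg
    n_voxels: np.ndarray
    vad_rmse: np.ndarray
    rain_fraction: float
    heights: np.ndarray = field(default_factory=lambda: HEIGHTS_M.copy())
    flags: list[str] = field(default_factory=list)


def beam_height(range_km, elevation_deg, radar_altitude_m: float = 0.0):
    """Height of the beam centre above radar level, meters.

    Standard 4/3-effective-Earth-radius propagation:
    ``h = sqrt(r^2 + k_a^2 + 2 r k_a sin(theta)) - k_a``.  The return
    is height above the antenna; callers treat it as height AGL at the
    station (``radar_altitude_m`` is accepted for interface symmetry
    but not added — profiles are station-relative).
    """
    r = np.asarray(range_km, dtype=float) * 1000.0
    theta = np.deg2rad(elevation_deg)
    h = np.sqrt(r**2 + K_A_M**2 + 2.0 * r * K_A_M * np.sin(theta)) - K_A_M
    return h if h.ndim else float(h)


def dbz_to_eta(dbz, wavelength_cm: float = WAVELENGTH_CM):
    """Linear reflectivity eta (cm^2 km^-3) from reflectivity factor (dBZ).

    eta = 10^3 * (pi^5 / lambda^4) * |K_m|^2 * 10^(dBZ/10), lambda in
    cm.  Missing reflectivity (NaN or -inf) maps to eta = 0 by
    convention: an empty voxel scatters nothing.
    """
    dbz = np.asarray(dbz, dtype=float)
    const = 1e3 * np.pi**5 / wavelength_cm**4 * KM2
    with np.errstate(invalid="ignore"):
        eta = const * 10.0 ** (dbz / 10.0)
    eta = np.where(np.isfinite(dbz), eta, 0.0)
    return eta if eta.ndim else float(eta)


def eta_to_dbz(eta, wavelength_cm: float = WAVELENGTH_CM):
    """Inverse of :func:`dbz_to_eta`; eta = 0 maps to -inf."""
    eta = np.asarray(eta, dtype=float)
    const = 1e3 * np.pi**5 / wavelength_cm**4 * KM2
    with np.errstate(divide="ignore"):
        dbz = 10.0 * np.log10(eta / const)
    return dbz if dbz.ndim else float(dbz)


def vad_fit(azimuth_deg, elevation_deg, vrad, min_voxels: int = 20):
    """Velocity-azimuth-display retrieval of horizontal wind.

    Least-squares fit of the two-parameter VAD model
    ``v_r = (u sin(az) + v cos(az)) cos(elev)`` over the supplied
    voxels.  Returns ``(u, v, speed, direction, rmse, n)`` with
    direction the compass bearing toward which movement occurs.
    Returns all-NaN (with the voxel count) when the system is
    underdetermined: fewer than ``min_voxels`` finite velocities, or
    no azimuthal diversity.
    """
    az = np.deg2rad(np.asarray(azimuth_deg, dtype=float))
    el = np.deg2rad(np.broadcast_to(np.asarray(elevation_deg, dtype=float), az.shape))
    vr = np.asarray(vrad, dtype=float)
    ok = np.isfinite(vr)
    az, el, vr = az[ok], el[ok], vr[ok]
    n = vr.size
    nan = (np.nan,) * 5
    if n < min_voxels:
        return (*nan, n)
    ce = np.cos(el)
    A = np.column_stack([np.sin(az) * ce, np.cos(az) * ce])
    if np.linalg.matrix_rank(A) < 2:
        return (*nan, n)
    coef, *_ = np.linalg.lstsq(A, vr, rcond=None)
    u, v = float(coef[0]), float(coef[1])
    resid = vr - A @ coef
    rmse = float(np.sqrt(np.mean(resid**2)))
    speed = float(np.hypot(u, v))
    direction = float(np.rad2deg(np.arctan2(u, v)) % 360.0)
    return u, v, speed, direction, rmse, n


@dataclass(frozen=True)
class ProfileOptions:
    """Knobs of profile assembly; defaults follow the five-lowest-sweep,
    2.5–50 km convention."""

    range_min_km: float = 2.5
    range_max_km: float = 50.0
    n_sweeps: int = 5
    min_vad_voxels: int = 20
    wavelength_cm: float = WAVELENGTH_CM


def build_profile(volume: PolarVolume, options: ProfileOptions | None = None) -> VerticalProfile:
    """Assemble a 30-bin vertical profile from a polar volume.

    Uses the ``n_sweeps`` lowest elevations and voxels with
    2.5 <= range <= 50 km.  Each voxel is assigned to the half-open
    100-m bin of its beam height; voxels at or above 3000 m are
    discarded.  Per bin, eta is the arithmetic mean over biology
    voxels plus missing voxels counted as zero (rain and clutter are
    excluded from eta entirely), and wind comes from a VAD fit over
    the bin's biology voxels.  The scan-level rain fraction is
    rain voxels / all classified voxels (biology + rain + clutter)
    across the retained sweeps and range window.
    """
    opt = options or ProfileOptions()
    if len(volume.sweeps) < opt.n_sweeps:
        warnings.warn(
            f"volume has {len(volume.sweeps)} sweeps; using all of them "
            f"(wanted {opt.n_sweeps})",
            stacklevel=2,
        )
    sweeps = volume.sweeps[: opt.n_sweeps]

    cols = {k: [] for k in ("height", "az", "elev", "eta", "vrad", "cls")}
    for sw in sweeps:
        az2d, rng2d = np.meshgrid(sw.azimuth_deg, sw.range_km, indexing="ij")
        in_range = (rng2d >= opt.range_min_km) & (rng2d <= opt.range_max_km)
        h = beam_height(rng2d[in_range], sw.elevation_deg)
        cols["height"].append(h)
        cols["az"].append(az2d[in_range])
        cols["elev"].append(np.full(h.shape, sw.elevation_deg))
        cols["eta"].append(dbz_to_eta(sw.dbz[in_range], opt.wavelength_cm))
        cols["vrad"].append(sw.vrad[in_range])
        cols["cls"].append(sw.voxel_class[in_range])
    height = np.concatenate(cols["height"])
    az = np.concatenate(cols["az"])
    elev = np.concatenate(cols["elev"])
    eta_vox = np.concatenate(cols["eta"])
    vrad = np.concatenate(cols["vrad"])
    cls = np.concatenate(cols["cls"])

    flags: list[str] = []
    classified = cls != VoxelClass.MISSING
    rain_fraction = float(np.mean(cls[classified] == VoxelClass.RAIN)) if classified.any() else np.nan

    below = height < N_BINS * BIN_SIZE_M
    bin_idx = np.floor(height / BIN_SIZE_M).astype(int)

    shape = (N_BINS,)
    eta = np.full(shape, np.nan)
    u = np.full(shape, np.nan)
    v = np.full(shape, np.nan)
    speed = np.full(shape, np.nan)
    direction = np.full(shape, np.nan)
    rmse = np.full(shape, np.nan)
    n_vox = np.zeros(shape, dtype=int)

    if not below.any():
        flags.append("no_voxels_in_range_window")
        return VerticalProfile(
            volume.timestamp, eta, u, v, speed, direction, n_vox, rmse, rain_fraction, flags=flags
        )

    for b in range(N_BINS):
        sel = below & (bin_idx == b)
        n_vox[b] = int(np.count_nonzero(sel))
        if not n_vox[b]:
            continue
        c = cls[sel]
        bio = c == VoxelClass.BIOLOGY
        miss = c == VoxelClass.MISSING
        denom = int(np.count_nonzero(bio) + np.count_nonzero(miss))
        if denom:
            # missing voxels contribute zero cross-section to the mean
            eta[b] = float(np.sum(eta_vox[sel][bio])) / denom
        if bio.any():
            fit = vad_fit(az[sel][bio], elev[sel][bio], vrad[sel][bio], opt.min_vad_voxels)
            u[b], v[b], speed[b], direction[b], rmse[b] = fit[:5]

    if np.all(np.isnan(eta)):
        flags.append("all_bins_missing")
    return VerticalProfile(
        volume.timestamp, eta, u, v, speed, direction, n_vox, rmse, rain_fraction, flags=flags
    )
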