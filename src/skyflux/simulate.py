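"""Synthetic radar observations with known diel and altitudinal structure.

The generator produces vertical-profile time series and polar volumes
from a forward model with known ground truth, so every downstream
stage — profile assembly, traffic rates, regularization, diel
partitioning, peak timing, envelopes — can be validated without any
radar archive.

Forward model
-------------
Activity at time ``t`` and height bin ``h`` factorises as

    eta(t, h) = A_noct * exp(-(HAS(t) - mu)^2 / (2 sigma^2)) * m_noct(h)
              + A_diur * 1[solar elevation >= 0] * m_diur(h)

where ``HAS(t)`` is hours after the most recent sunset, so the
nocturnal pulse tracks sunset across latitude and season, and
``m(h)`` are per-bin masses of a truncated Gaussian (or gamma)
altitude density on [0, 3000) m that sum to one.  Winds are a
piecewise-linear function of height.  Observation noise is
multiplicative lognormal on eta (mean one, so unbiased) and additive
Gaussian on radial velocity.  Scan cadence is irregular (mean ~6 min,
uniform jitter).  Rain contamination is injected as episodes that set
a fraction of voxels (or the scan-level rain fraction) to the rain
class; overlapping episodes combine by maximum fraction.

Ground truth (peak offset, 50% altitude envelope, percent nocturnal,
per-bin wind) is computed from the noise-free model on the same 5-min
grid the pipeline uses.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import solar
from .envelope import scan_envelope
from .profiles import PolarVolume, Sweep, VoxelClass, eta_to_dbz
from .series import BIN_SIZE_M, HEIGHTS_M, N_BINS, ProfileSeries, Station
from .traffic import BIN_DEPTH_KM, MPS_TO_KMH

__all__ = [
    "SimulationConfig",
    "RainEpisode",
    "GroundTruth",
    "simulate_profile_series",
    "simulate_polar_volume",
    "inject_rain",
    "diurnal_amplitude_for_nocturnality",
]

#: Default station: central-Oklahoma prairie site (KTLX-like position).
DEFAULT_STATION = Station("SYNTH", 35.333, -97.278, 370.0)

DEFAULT_ELEVATIONS = (0.5, 0.9, 1.3, 1.8, 2.4)


@dataclass(frozen=True)
class RainEpisode:
    """A contamination episode: scans in [start, end] get this rain fraction."""

    start: pd.Timestamp
    end: pd.Timestamp
    fraction: float

    def __post_init__(self):
        object.__setattr__(self, "start", pd.Timestamp(self.start))
        object.__setattr__(self, "end", pd.Timestamp(self.end))
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"rain fraction {self.fraction} outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the forward model; defaults are one realistic
    migration month at a mid-latitude station.

    Amplitudes are column-total eta (cm^2 km^-3 summed over bins) at
    the pulse peak / during daylight.  Altitude modes and spreads are
    meters AGL, one pair per diel phase.  ``wind_profile`` is a list
    of (height_m, u_mps, v_mps) nodes interpolated linearly in height.
    """

    station: Station = DEFAULT_STATION
    start_date: dt.date = dt.date(2022, 4, 1)
    end_date: dt.date = dt.date(2022, 4, 30)
    scan_interval_mean: float = 6.0  # minutes
    scan_interval_jitter: float = 2.0  # +/- minutes, uniform
    nocturnal_peak_offset: float = 4.0  # hours after sunset
    nocturnal_pulse_sd: float = 2.0  # hours
    nocturnal_amplitude: float = 500.0
    diurnal_amplitude: float = 50.0
    nocturnal_altitude_mode: float = 600.0
    nocturnal_altitude_spread: float = 400.0
    diurnal_altitude_mode: float = 400.0
    diurnal_altitude_spread: float = 500.0
    altitude_family: str = "truncnorm"  # or "gamma"
    wind_profile: tuple = ((0.0, 2.0, 4.0), (1500.0, 8.0, 9.0), (3000.0, 11.0, 10.0))
    rain_episodes: tuple = ()
    noise_sd: float = 0.2  # lognormal sigma on eta
    velocity_noise_sd: float = 0.5  # m/s, additive on radial velocity
    elevations_deg: tuple = DEFAULT_ELEVATIONS
    range_step_km: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.end_date < self.start_date:
            raise ValueError("empty date range: end_date before start_date")
        if self.nocturnal_amplitude < 0 or self.diurnal_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.nocturnal_pulse_sd <= 0:
            raise ValueError("nocturnal_pulse_sd must be positive")
        for mode in (self.nocturnal_altitude_mode, self.diurnal_altitude_mode):
            if not 0.0 <= mode < N_BINS * BIN_SIZE_M:
                raise ValueError(f"altitude mode {mode} outside [0, 3000)")
        if self.noise_sd < 0 or self.velocity_noise_sd < 0:
            raise ValueError("noise scales must be non-negative")

    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        start = pd.Timestamp(self.start_date)
        return start, pd.Timestamp(self.end_date) + pd.Timedelta(days=1)


@dataclass
class GroundTruth:
    """Noise-free estimands of a simulated series."""

    true_peak_offset: float  # hours after sunset
    true_envelope: tuple | None  # (lower_m, upper_m) of the 50% band
    true_percent_nocturnal: float  # NaN when total passage is zero
    true_wind: np.ndarray  # (30, 2) per-bin (u, v)
    flags: list = field(default_factory=list)


def _altitude_masses(mode: float, spread: float, family: str = "truncnorm") -> np.ndarray:
    """Per-bin masses of the altitude density on [0, 3000); sums to 1."""
    edges = np.arange(N_BINS + 1) * BIN_SIZE_M
    top = N_BINS * BIN_SIZE_M
    if family == "truncnorm":
        a, b = (0.0 - mode) / spread, (top - mode) / spread
        cdf = stats.truncnorm.cdf(edges, a, b, loc=mode, scale=spread)
    elif family == "gamma":
        # shape/scale chosen so the mode and SD match the requested ones
        k = 1.0 + (mode / spread) ** 2 / 2 + np.sqrt((mode / spread) ** 2 + (mode / spread) ** 4 / 4)
        theta = mode / (k - 1.0) if k > 1 else spread
        cdf = stats.gamma.cdf(edges, k, scale=theta)
        cdf = cdf / cdf[-1]
    else:
        raise ValueError(f"unknown altitude family {family!r}")
    masses = np.diff(cdf)
    return masses / masses.sum()


def _wind_at(config: SimulationConfig, heights_m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.asarray(config.wind_profile, dtype=float)
    order = np.argsort(nodes[:, 0])
    h, u, v = nodes[order, 0], nodes[order, 1], nodes[order, 2]
    return np.interp(heights_m, h, u), np.interp(heights_m, h, v)


def _diel_weights(config: SimulationConfig, times: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """(nocturnal pulse weight, diurnal baseline weight) per timestamp."""
    lat, lon = config.station.latitude, config.station.longitude
    elev = solar.solar_elevation(lat, lon, times)
    has = np.array([solar.hours_after_sunset(lat, lon, t) for t in times])
    pulse = np.exp(-((has - config.nocturnal_peak_offset) ** 2) / (2.0 * config.nocturnal_pulse_sd**2))
    # each component is active only in its own diel phase: the pulse is a
    # nocturnal phenomenon, the baseline a daylight one
    pulse = np.where(elev < 0.0, pulse, 0.0)
    baseline = (elev >= 0.0).astype(float)
    return config.nocturnal_amplitude * pulse, config.diurnal_amplitude * baseline


def _model_eta(config: SimulationConfig, times: pd.DatetimeIndex) -> np.ndarray:
    """Noise-free per-bin eta, shape (n_times, 30)."""
    w_noct, w_diur = _diel_weights(config, times)
    m_noct = _altitude_masses(
        config.nocturnal_altitude_mode, config.nocturnal_altitude_spread, config.altitude_family
    )
    m_diur = _altitude_masses(
        config.diurnal_altitude_mode, config.diurnal_altitude_spread, config.altitude_family
    )
    return np.outer(w_noct, m_noct) + np.outer(w_diur, m_diur)


def _bin_centers() -> np.ndarray:
    return HEIGHTS_M + BIN_SIZE_M / 2.0


def _scan_times(config: SimulationConfig, rng: np.random.Generator) -> pd.DatetimeIndex:
    start, end = config.span()
    times = []
    t = start
    while t < end:
        times.append(t.round("s"))  # radar clocks report whole seconds
        jitter = rng.uniform(-config.scan_interval_jitter, config.scan_interval_jitter)
        step = max(1.0, config.scan_interval_mean + jitter)
        t = t + pd.Timedelta(minutes=step)
    return pd.DatetimeIndex(times)


def _truth_grid(config: SimulationConfig) -> pd.DatetimeIndex:
    """5-min grid over the complete 20:00-19:59 UTC sampling windows of
    the span — the estimand the pipeline actually measures.  Falls back
    to the full span when no complete window fits."""
    start, end = config.span()
    first = start.normalize() + pd.Timedelta(hours=20)
    if first < start:
        first += pd.Timedelta(days=1)
    last = first
    while last + pd.Timedelta(days=1) <= end:
        last += pd.Timedelta(days=1)
    if last == first:
        return pd.date_range(start, end, freq="5min", inclusive="left")
    return pd.date_range(first, last, freq="5min", inclusive="left")


def _ground_truth(config: SimulationConfig) -> GroundTruth:
    centers = _bin_centers()
    u, v = _wind_at(config, centers)
    speed_kmh = np.hypot(u, v) * MPS_TO_KMH
    flags = []

    m_noct = _altitude_masses(
        config.nocturnal_altitude_mode, config.nocturnal_altitude_spread, config.altitude_family
    )
    noct_rtr_shape = m_noct * speed_kmh * BIN_DEPTH_KM
    if config.nocturnal_amplitude > 0:
        env = scan_envelope(noct_rtr_shape, 0.5)
        true_env = (env.lower_m, env.upper_m)
    else:
        true_env = None
        flags.append("envelope_undefined_zero_nocturnal_mass")

    # Percent nocturnal of the noise-free model on the pipeline's 5-min
    # grid, restricted to complete sampling windows (the pipeline's own
    # analysis domain).
    grid = _truth_grid(config)
    eta = _model_eta(config, grid)
    total_rtr = eta @ (speed_kmh * BIN_DEPTH_KM)
    elev = solar.solar_elevation(config.station.latitude, config.station.longitude, grid)
    nocturnal = elev < 0.0
    total = float(total_rtr.sum())
    if total > 0:
        pct = 100.0 * float(total_rtr[nocturnal].sum()) / total
    else:
        pct = np.nan
        flags.append("percent_nocturnal_undefined_zero_passage")
    return GroundTruth(config.nocturnal_peak_offset, true_env, pct, np.column_stack([u, v]), flags)


def simulate_profile_series(config: SimulationConfig) -> tuple[ProfileSeries, GroundTruth]:
    """Simulate an irregular vertical-profile time series.

    Returns the series and the ground truth of its noise-free model.
    Identical configs (including seed) give bitwise-identical output.
    """
    rng = np.random.default_rng(config.seed)
    times = _scan_times(config, rng)
    n = len(times)
    eta = _model_eta(config, times)
    if config.noise_sd > 0:
        s = config.noise_sd
        eta = eta * np.exp(rng.normal(-0.5 * s * s, s, size=eta.shape))

    centers = _bin_centers()
    u, v = _wind_at(config, centers)
    speed = np.hypot(u, v)
    direction = np.rad2deg(np.arctan2(u, v)) % 360.0
    # plausible voxel support: densest sampling in the lowest bins
    n_voxels = np.round(np.linspace(26000, 14000, N_BINS)).astype(int)

    df = pd.DataFrame(
        {
            "datetime": np.repeat(times, N_BINS),
            "height": np.tile(HEIGHTS_M, n),
            "eta": eta.ravel(),
            "u": np.tile(u, n),
            "v": np.tile(v, n),
            "ground_speed": np.tile(speed, n),
            "direction": np.tile(direction, n),
            "n_voxels": np.tile(n_voxels, n),
            "rain_fraction": 0.0,
        }
    )
    series = ProfileSeries(config.station, df)
    if config.rain_episodes:
        series = inject_rain(series, config.rain_episodes)
    return series, _ground_truth(config)


def inject_rain(series: ProfileSeries, episodes) -> ProfileSeries:
    """Stamp rain fractions onto the scans covered by each episode.

    Overlapping episodes combine by maximum fraction.  Episodes that
    touch no scan in the series span are ignored with a warning.
    """
    df = series.df.copy()
    t = df["datetime"]
    for ep in episodes:
        ep = ep if isinstance(ep, RainEpisode) else RainEpisode(*ep)
        hit = (t >= ep.start) & (t <= ep.end)
        if not hit.any():
            warnings.warn(f"rain episode {ep.start}..{ep.end} outside series span; ignored",
                          stacklevel=2)
            continue
        df.loc[hit, "rain_fraction"] = np.maximum(df.loc[hit, "rain_fraction"], ep.fraction)
    return ProfileSeries(series.station, df)


def simulate_polar_volume(config: SimulationConfig, time) -> PolarVolume:
    """Simulate one polar volume (five sweeps) at a given UTC time.

    Voxel reflectivity follows the bin value of the noise-free model
    (times lognormal noise when configured), expressed as dBZ via the
    inverse eta conversion; radial velocity is the VAD projection of
    the height-dependent wind plus Gaussian noise.  Rain episodes
    covering ``time`` label a random voxel fraction as rain.
    """
    time = pd.Timestamp(time)
    start, end = config.span()
    if not (start <= time < end):
        raise ValueError(f"time {time} outside simulated date range [{start}, {end})")
    rng = np.random.default_rng([config.seed, int(time.value) % (2**31)])

    eta_bins = _model_eta(config, pd.DatetimeIndex([time]))[0]
    rain_frac = 0.0
    for ep in config.rain_episodes:
        ep = ep if isinstance(ep, RainEpisode) else RainEpisode(*ep)
        if ep.start <= time <= ep.end:
            rain_frac = max(rain_frac, ep.fraction)

    azimuths = np.arange(0.0, 360.0, 1.0)
    ranges = np.arange(2.5, 50.0 + 1e-9, config.range_step_km)
    sweeps = []
    for elev_deg in config.elevations_deg:
        from .profiles import beam_height  # local import avoids cycle at module load

        h = beam_height(ranges, elev_deg)
        bin_idx = np.minimum((h // BIN_SIZE_M).astype(int), N_BINS)  # N_BINS = above 3000 m
        eta_gate = np.where(bin_idx < N_BINS, eta_bins[np.minimum(bin_idx, N_BINS - 1)], 0.0)
        eta_vox = np.broadcast_to(eta_gate, (len(azimuths), len(ranges))).copy()
        if config.noise_sd > 0:
            s = config.noise_sd
            eta_vox *= np.exp(rng.normal(-0.5 * s * s, s, size=eta_vox.shape))
        with np.errstate(divide="ignore"):
            dbz = eta_to_dbz(eta_vox)
        dbz = np.where(np.isfinite(dbz), dbz, np.nan)

        u, v = _wind_at(config, np.minimum(h, N_BINS * BIN_SIZE_M))
        az_rad = np.deg2rad(azimuths)[:, None]
        vrad = (u[None, :] * np.sin(az_rad) + v[None, :] * np.cos(az_rad)) * np.cos(
            np.deg2rad(elev_deg)
        )
        if config.velocity_noise_sd > 0:
            vrad = vrad + rng.normal(0.0, config.velocity_noise_sd, size=vrad.shape)

        voxel_class = np.full(eta_vox.shape, int(VoxelClass.BIOLOGY), dtype=np.int8)
        if rain_frac > 0:
            voxel_class[rng.random(eta_vox.shape) < rain_frac] = int(VoxelClass.RAIN)
        sweeps.append(Sweep(elev_deg, azimuths, ranges, dbz, vrad, voxel_class))
    return PolarVolume(config.station, time, sweeps)


def diurnal_amplitude_for_nocturnality(config: SimulationConfig, target_percent: float) -> float:
    """Diurnal amplitude that makes the noise-free model's percent
    nocturnal equal ``target_percent``.

    The seasonal percent is 100*N_n / (N_n + N_d + a*D) where N_n and
    N_d are the nocturnal pulse's passage falling in nocturnal and
    diurnal slots and D the baseline passage per unit amplitude, so
    the required amplitude has a closed form.  Returns 0 (with a
    warning) when the pulse's diurnal leakage alone already exceeds
    the target.
    """
    if not 0.0 < target_percent <= 100.0:
        raise ValueError("target percent must be in (0, 100]")
    centers = _bin_centers()
    u, v = _wind_at(config, centers)
    w = np.hypot(u, v) * MPS_TO_KMH * BIN_DEPTH_KM

    grid = _truth_grid(config)
    noct_cfg = replace(config, diurnal_amplitude=0.0)
    pulse_rtr = _model_eta(noct_cfg, grid) @ w
    base_cfg = replace(config, diurnal_amplitude=1.0, nocturnal_amplitude=0.0)
    base_rtr = _model_eta(base_cfg, grid) @ w

    elev = solar.solar_elevation(config.station.latitude, config.station.longitude, grid)
    noct = elev < 0.0
    N_n = float(pulse_rtr[noct].sum())
    N_d = float(pulse_rtr[~noct].sum())
    D = float(base_rtr.sum())
    if D <= 0:
        raise ValueError("baseline passage is zero; cannot calibrate")
    a = (N_n * (100.0 - target_percent) / target_percent - N_d) / D
    if a < 0:
        warnings.warn(
            f"pulse leakage alone gives < {target_percent}% nocturnal; clamping amplitude to 0",
            stacklevel=2,
        )
        return 0.0
    return a
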