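"""Reflectivity traffic rate.

The traffic rate converts a vertical profile of linear reflectivity
eta (cm^2 km^-3) and groundspeed into the total scattering
cross-section (cm^2) crossing a 1-km transect per hour:

    rtr_i = eta_i * s_i * dh,   rtr = sum_i rtr_i

with s_i the bin groundspeed in km/h and dh = 0.1 km the bin depth.
The transect is, by construction, perpendicular to the mean travel
direction in each bin: using the scalar groundspeed measures the flux
magnitude through that direction-normal transect, so only speed — not
direction — enters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profiles import VerticalProfile
from .series import BIN_SIZE_M, ProfileSeries

__all__ = ["TrafficRate", "traffic_rate", "add_traffic_rates", "MPS_TO_KMH", "BIN_DEPTH_KM"]

MPS_TO_KMH = 3.6
BIN_DEPTH_KM = BIN_SIZE_M / 1000.0


@dataclass
class TrafficRate:
    """Per-bin and column-total reflectivity traffic rate of one scan."""

    timestamp: object
    per_bin_rtr: np.ndarray  # cm^2 km^-1 h^-1 per 100-m bin
    total_rtr: float
    #: bins with reflectivity but no wind solution; they contribute 0
    uncovered_bins: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    missing: bool = False
    reason: str = ""


def _rtr_bins(eta: np.ndarray, ground_speed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    eta = np.asarray(eta, dtype=float)
    gs = np.asarray(ground_speed, dtype=float)
    rtr = eta * gs * MPS_TO_KMH * BIN_DEPTH_KM
    uncovered = np.flatnonzero(np.isfinite(eta) & (eta > 0) & ~np.isfinite(gs))
    rtr = np.where(np.isfinite(rtr), rtr, 0.0)
    rtr = np.where(np.isfinite(eta), rtr, 0.0)
    return rtr, uncovered


def traffic_rate(profile: VerticalProfile) -> TrafficRate:
    """Traffic rate of one vertical profile.

    Bins missing either eta or a VAD wind solution contribute zero;
    bins with positive eta but no wind are flagged in
    ``uncovered_bins`` (conservative: no speed imputation).  A profile
    with no usable bin at all yields a missing rate with a reason
    code.
    """
    usable = np.isfinite(profile.eta) & np.isfinite(profile.ground_speed)
    if not usable.any():
        return TrafficRate(
            profile.timestamp,
            np.zeros_like(profile.eta),
            np.nan,
            missing=True,
            reason="no bin with both eta and groundspeed",
        )
    rtr, uncovered = _rtr_bins(profile.eta, profile.ground_speed)
    return TrafficRate(profile.timestamp, rtr, float(np.sum(rtr)), uncovered)


def add_traffic_rates(series: ProfileSeries) -> ProfileSeries:
    """Append per-bin (``rtr_bin``) and per-scan (``rtr_total``) traffic
    rates to a profile series, vectorised over all scans."""
    df = series.df.copy()
    rtr, _ = _rtr_bins(df["eta"].to_numpy(), df["ground_speed"].to_numpy())
    df["rtr_bin"] = rtr
    df["rtr_total"] = df.groupby("datetime")["rtr_bin"].transform("sum")
    return ProfileSeries(series.station, df)
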