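"""Minimal altitude envelopes of aerial activity.

The envelope of a scan is the narrowest contiguous band of 100-m
height bins whose activity (per-bin traffic rate) sums to at least a
target fraction ``q`` of the column total — the vertical space that
captures, e.g., 50% of migrant passage.  Ties between equally narrow
bands break toward the lowest starting height.  Envelopes are
reported at bin resolution: bounds are multiples of 100 m.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .series import BIN_SIZE_M, N_BINS

__all__ = ["Envelope", "scan_envelope", "peak_window_slots", "mean_envelope", "pooled_envelope"]

_REL_TOL = 1e-9  # guards >= comparisons against float summation error


@dataclass
class Envelope:
    """A half-open altitude band [lower, upper) and what it captures."""

    lower_m: float
    upper_m: float
    fraction_captured: float
    q_target: float
    n_scans: int = 1
    lower_sd_m: float = np.nan
    upper_sd_m: float = np.nan
    flags: list = field(default_factory=list)

    @property
    def width_m(self) -> float:
        return self.upper_m - self.lower_m


def scan_envelope(per_bin_activity, q: float) -> Envelope:
    """Minimal contiguous window of bins holding a fraction q of activity.

    Scans window widths from 1 bin upward and returns the first
    (hence minimal-width) window reaching ``q`` of the total, taking
    the lowest start among equal widths.  Raises ``ValueError`` for an
    all-zero or invalid profile.
    """
    a = np.asarray(per_bin_activity, dtype=float)
    if a.shape != (N_BINS,):
        raise ValueError(f"expected {N_BINS} bins, got shape {a.shape}")
    a = np.where(np.isfinite(a), a, 0.0)
    if (a < 0).any():
        raise ValueError("activity must be non-negative")
    total = a.sum()
    if total <= 0:
        raise ValueError("all-zero activity profile: envelope undefined")
    if not 0.0 < q <= 1.0:
        raise ValueError(f"q must be in (0, 1], got {q}")

    need = q * (1.0 - _REL_TOL)
    cum = np.concatenate([[0.0], np.cumsum(a)])
    for width in range(1, N_BINS + 1):
        sums = cum[width:] - cum[:-width]
        hits = np.flatnonzero(sums / total >= need)
        if hits.size:
            lo = int(hits[0])
            return Envelope(
                lower_m=lo * BIN_SIZE_M,
                upper_m=(lo + width) * BIN_SIZE_M,
                fraction_captured=float(sums[lo] / total),
                q_target=q,
            )
    raise AssertionError("unreachable: full window always reaches q <= 1")


def peak_window_slots(
    diel_context: pd.DataFrame,
    peak_hours: float,
    sd_hours: float,
    selected_days=None,
    day_labels=None,
    min_half_width: float = 0.5,
) -> tuple[pd.DatetimeIndex, list]:
    """Slots falling inside the peak-activity window peak +/- 1 SD.

    ``diel_context`` is indexed by slot time with a
    ``hours_after_sunset`` column.  When ``selected_days`` and
    ``day_labels`` (the sampling-day label of each slot) are given,
    only slots on those days qualify.  A zero SD (single year) falls
    back to ``min_half_width`` hours, flagged.  The window is not
    truncated at sunrise: it is a window in hours after sunset.
    """
    flags = []
    half = sd_hours
    if not np.isfinite(half) or half <= 0:
        half = min_half_width
        flags.append("zero_sd_default_half_width")
    has = diel_context["hours_after_sunset"]
    mask = (has >= peak_hours - half) & (has <= peak_hours + half)
    if selected_days is not None:
        if day_labels is None:
            raise ValueError("selected_days requires day_labels")
        mask &= pd.Series(day_labels, index=diel_context.index).isin(list(selected_days))
    slots = diel_context.index[mask]
    if len(slots) == 0:
        flags.append("empty_peak_window")
    return slots, flags


def mean_envelope(envelopes: list[Envelope]) -> Envelope:
    """Mean of scan-level envelope bounds (the scan-mean summary).

    Lower and upper bounds are averaged separately; the width is the
    difference of the means, and SDs of both bounds are reported.
    """
    if not envelopes:
        raise ValueError("no scan envelopes to summarize")
    lowers = np.array([e.lower_m for e in envelopes], dtype=float)
    uppers = np.array([e.upper_m for e in envelopes], dtype=float)
    q = envelopes[0].q_target
    return Envelope(
        lower_m=float(lowers.mean()),
        upper_m=float(uppers.mean()),
        fraction_captured=float(np.mean([e.fraction_captured for e in envelopes])),
        q_target=q,
        n_scans=len(envelopes),
        lower_sd_m=float(lowers.std(ddof=1)) if len(envelopes) > 1 else 0.0,
        upper_sd_m=float(uppers.std(ddof=1)) if len(envelopes) > 1 else 0.0,
    )


def pooled_envelope(per_bin_activities, q: float) -> Envelope:
    """Envelope of the passage summed across scans.

    Per-bin activities (n_scans x 30) are summed over scans first and
    a single envelope taken of the pooled profile — the alternative
    summary to the mean of scan-level envelopes.
    """
    arr = np.atleast_2d(np.asarray(per_bin_activities, dtype=float))
    arr = np.where(np.isfinite(arr), arr, 0.0)
    env = scan_envelope(arr.sum(axis=0), q)
    env.n_scans = arr.shape[0]
    return env
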