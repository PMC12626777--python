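"""Diurnal/nocturnal partitioning of passage.

The headline metric is the *seasonal* percent nocturnal: summed
nocturnal traffic over summed total traffic across all retained
sampling days of a station–season–year.  Weighting by passage keeps
the metric faithful to the migration system's dominant behaviour: a
day with 10 animals and a day with 10,000 contribute in proportion to
their passage, not equally.  The contrasting unweighted mean of daily
percentages is provided as a diagnostic; the seasonal metric equals
the passage-weighted mean of the daily percentages exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .regularize import RegularSeries

__all__ = ["DielSummary", "percent_nocturnal_seasonal", "percent_nocturnal_daily_mean",
           "phase_sums_by_day", "pooled_percent_nocturnal"]


@dataclass
class DielSummary:
    """Seasonal diel partition for one station–season–year."""

    station: str
    season: str
    year: int
    sum_nocturnal: float
    sum_diurnal: float
    percent_nocturnal_seasonal: float  # NaN when total passage is zero
    percent_nocturnal_daily_mean: float  # diagnostic, unweighted over days
    n_days: int
    flags: list = field(default_factory=list)


def phase_sums_by_day(reg: RegularSeries, diel_context: pd.DataFrame) -> pd.DataFrame:
    """Per retained sampling day: nocturnal, diurnal and total passage.

    Only valid slots (gap-filled, not rain-excluded) on retained days
    contribute; excluded slots enter neither numerator nor
    denominator.
    """
    days = reg.day_summary
    retained = days.index[days["retained"]]
    slots = reg.slots
    use = slots["valid"] & slots["sampling_day"].isin(retained)
    sub = slots.loc[use, ["total_rtr", "sampling_day"]].copy()
    phase = diel_context["phase"].reindex(sub.index)
    sub["nocturnal_rtr"] = np.where(phase == "nocturnal", sub["total_rtr"], 0.0)
    out = sub.groupby("sampling_day").agg(
        total=("total_rtr", "sum"), nocturnal=("nocturnal_rtr", "sum")
    )
    out["diurnal"] = out["total"] - out["nocturnal"]
    return out


def percent_nocturnal_seasonal(
    reg: RegularSeries,
    diel_context: pd.DataFrame,
    station: str = "",
    season: str = "",
    year: int = 0,
) -> DielSummary:
    """Seasonal percent nocturnal: 100 * sum(nocturnal) / sum(all)."""
    by_day = phase_sums_by_day(reg, diel_context)
    flags = []
    noct = float(by_day["nocturnal"].sum())
    diur = float(by_day["diurnal"].sum())
    total = noct + diur
    if total > 0:
        pct = 100.0 * noct / total
    else:
        pct = np.nan
        flags.append("zero_total_passage")
    return DielSummary(
        station,
        season,
        year,
        noct,
        diur,
        pct,
        percent_nocturnal_daily_mean(by_day),
        n_days=len(by_day),
        flags=flags,
    )


def percent_nocturnal_daily_mean(by_day: pd.DataFrame) -> float:
    """Unweighted mean of per-day percent nocturnal.

    Days with zero passage have no defined percentage and are
    excluded.  This diagnostic gives even weight to days regardless of
    how much passage they carry.
    """
    pos = by_day[by_day["total"] > 0]
    if len(pos) == 0:
        return np.nan
    return float((100.0 * pos["nocturnal"] / pos["total"]).mean())


def pooled_percent_nocturnal(summaries: list[DielSummary]) -> tuple[float, float]:
    """Multi-station pooling, both ways.

    Returns ``(passage_weighted, station_mean)``: the former sums
    passage across stations before taking the percentage, the latter
    averages station-level percentages.
    """
    noct = sum(s.sum_nocturnal for s in summaries)
    total = sum(s.sum_nocturnal + s.sum_diurnal for s in summaries)
    weighted = 100.0 * noct / total if total > 0 else np.nan
    pcts = [s.percent_nocturnal_seasonal for s in summaries
            if np.isfinite(s.percent_nocturnal_seasonal)]
    mean = float(np.mean(pcts)) if pcts else np.nan
    return weighted, mean
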