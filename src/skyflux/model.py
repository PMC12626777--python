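"""End-to-end model of diel airspace use at one radar station.

:class:`DielAirspaceModel` takes a vertical-profile time series and,
on ``fit()``, runs the full chain — traffic rates, 5-min
regularization, rain/completeness QC, solar phase assignment — then
estimates, per season–year, the seasonal percent nocturnal, the
peak-activity hour after sunset (penalized cyclic-spline smooth on
top-quartile days, variance-explained and minimum-day QC), and the
minimal altitude envelopes of passage inside the peak window
(peak +/- 1 SD across years).  The returned
:class:`DielAirspaceResults` carries the estimates with their
uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar
from .diel import DielSummary, percent_nocturnal_seasonal
from .envelope import Envelope, mean_envelope, peak_window_slots, pooled_envelope, scan_envelope
from .peaks import PeakAggregate, PeakEstimate, aggregate_peaks, fit_activity_curve
from .regularize import RegularSeries, regularize, sampling_days
from .series import ProfileSeries
from .traffic import add_traffic_rates

__all__ = ["PipelineConfig", "DielAirspaceModel", "DielAirspaceResults"]


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-side knobs (QC thresholds live with their modules)."""

    regularize_method: str = "nearest"  # or 'linear'
    response_transform: str = "sqrt"  # or 'identity'
    spline_df: int = 40
    envelope_q: tuple = (0.5, 0.75)
    min_peak_half_width_h: float = 0.5


def _group_view(reg: RegularSeries, days: pd.DatetimeIndex) -> RegularSeries:
    """Restrict a regular series to the given sampling days."""
    mask = reg.slots["sampling_day"].isin(days)
    sub = RegularSeries(reg.station, reg.slots.loc[mask], reg.rtr_bins[mask.to_numpy()])
    sub.day_summary = sampling_days(sub)
    return sub


class DielAirspaceModel:
    """Diel airspace use fitted to one station's profile series.

    Parameters
    ----------
    series : ProfileSeries
        Irregular vertical-profile series; traffic rates are added if
        absent.
    pipeline : PipelineConfig, optional
    """

    def __init__(self, series: ProfileSeries, pipeline: PipelineConfig | None = None):
        if "rtr_total" not in series.df.columns:
            series = add_traffic_rates(series)
        self.series = series
        self.pipeline = pipeline or PipelineConfig()

    @classmethod
    def from_vpts(cls, path, pipeline: PipelineConfig | None = None) -> "DielAirspaceModel":
        from .io import read_vpts

        return cls(read_vpts(path), pipeline)

    def fit(self) -> "DielAirspaceResults":
        cfg = self.pipeline
        st = self.series.station
        reg = regularize(self.series, method=cfg.regularize_method)
        ctx = solar.assign_phase(reg.grid, st.latitude, st.longitude)

        days = reg.day_summary
        retained = days.index[days["retained"]]
        groups: dict[tuple[str, int], pd.DatetimeIndex] = {}
        for day in retained:
            season = solar.season_of(day.date())
            if season == "none":
                continue
            groups.setdefault((season, day.year), []).append(day)

        diel_summaries: list[DielSummary] = []
        peak_estimates: list[PeakEstimate] = []
        for (season, year), group_days in sorted(groups.items()):
            group_days = pd.DatetimeIndex(group_days)
            sub = _group_view(reg, group_days)
            diel_summaries.append(
                percent_nocturnal_seasonal(sub, ctx, st.name, season, year)
            )
            use = sub.slots["valid"]
            peak_estimates.append(
                fit_activity_curve(
                    sub.slots.loc[use, "total_rtr"],
                    ctx.loc[use[use].index, "hours_after_sunset"],
                    sub.slots.loc[use, "sampling_day"],
                    st.name, season, year,
                    transform=cfg.response_transform, df=cfg.spline_df,
                )
            )

        peak_aggregates: list[PeakAggregate] = []
        envelopes: list[dict] = []
        for season in sorted({s for s, _ in groups}):
            season_est = [e for e in peak_estimates if e.season == season]
            try:
                agg = aggregate_peaks(season_est)
            except ValueError:
                continue
            peak_aggregates.append(agg)
            for est in season_est:
                if not est.qc_pass:
                    continue
                group_days = groups[(season, est.year)]
                sub = _group_view(reg, pd.DatetimeIndex(group_days))
                slots_idx, flags = peak_window_slots(
                    ctx.loc[sub.slots.index[sub.slots["valid"]]],
                    agg.mean_peak, agg.sd_peak,
                    selected_days=est.selected_days,
                    day_labels=sub.slots.loc[sub.slots["valid"], "sampling_day"],
                    min_half_width=cfg.min_peak_half_width_h,
                )
                if len(slots_idx) == 0:
                    continue
                pos = sub.slots.index.get_indexer(slots_idx)
                acts = sub.rtr_bins[pos]
                keep = np.nansum(acts, axis=1) > 0
                acts = acts[keep]
                if not len(acts):
                    continue
                for q in cfg.envelope_q:
                    scan_envs = [scan_envelope(a, q) for a in acts]
                    envelopes.append(
                        {
                            "station": st.name, "season": season, "year": est.year,
                            "q": q, "n_scans": len(scan_envs),
                            "mean": mean_envelope(scan_envs),
                            "pooled": pooled_envelope(acts, q),
                            "window_flags": flags,
                        }
                    )
        return DielAirspaceResults(
            self, reg, ctx, diel_summaries, peak_estimates, peak_aggregates, envelopes
        )


@dataclass
class DielAirspaceResults:
    """Fitted diel airspace use: tables of estimates with QC."""

    model: DielAirspaceModel
    regular: RegularSeries
    diel_context: pd.DataFrame = field(repr=False)
    diel_summaries: list = field(default_factory=list)
    peak_estimates: list = field(default_factory=list)
    peak_aggregates: list = field(default_factory=list)
    envelopes: list = field(default_factory=list)

    @property
    def diel_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "station": s.station, "season": s.season, "year": s.year,
                    "percent_nocturnal": s.percent_nocturnal_seasonal,
                    "percent_nocturnal_daily_mean": s.percent_nocturnal_daily_mean,
                    "n_days": s.n_days,
                }
                for s in self.diel_summaries
            ]
        )

    @property
    def peak_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "station": e.station, "season": e.season, "year": e.year,
                    "peak_hours_after_sunset": e.peak_hours_after_sunset,
                    "variance_explained": e.variance_explained,
                    "n_days_used": e.n_days_used, "qc_pass": e.qc_pass,
                }
                for e in self.peak_estimates
            ]
        )

    @property
    def envelope_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.envelopes:
            for kind in ("mean", "pooled"):
                env: Envelope = rec[kind]
                rows.append(
                    {
                        "station": rec["station"], "season": rec["season"],
                        "year": rec["year"], "q": rec["q"], "summary": kind,
                        "lower_m": env.lower_m, "upper_m": env.upper_m,
                        "width_m": env.width_m, "n_scans": rec["n_scans"],
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        st = self.model.series.station
        days = self.regular.day_summary
        lines = [
            f"Diel airspace use — station {st.name} "
            f"({st.latitude:.3f}, {st.longitude:.3f})",
            f"  scans: {len(self.model.series)}; grid slots: {len(self.regular.grid)}; "
            f"sampling days retained: {int(days['retained'].sum())}/{int(days['complete'].sum())}",
            "",
        ]
        for s in self.diel_summaries:
            lines.append(
                f"  {s.season} {s.year}: {s.percent_nocturnal_seasonal:.1f}% nocturnal "
                f"(daily-mean diagnostic {s.percent_nocturnal_daily_mean:.1f}%, "
                f"{s.n_days} days)"
            )
        for e in self.peak_estimates:
            status = "ok" if e.qc_pass else "QC-FAIL"
            peak = f"{e.peak_hours_after_sunset:.1f} h" if np.isfinite(
                e.peak_hours_after_sunset) else "--"
            ve = f"{100 * e.variance_explained:.0f}%" if np.isfinite(e.variance_explained) else "--"
            lines.append(
                f"  {e.season} {e.year}: peak {peak} after sunset "
                f"(variance explained {ve}, {e.n_days_used} days, {status})"
            )
        for a in self.peak_aggregates:
            lines.append(
                f"  {a.season}: mean peak {a.mean_peak:.1f} ± {a.sd_peak:.1f} h "
                f"({a.n_years} year{'s' if a.n_years != 1 else ''})"
            )
        for rec in self.envelopes:
            env: Envelope = rec["mean"]
            lines.append(
                f"  {rec['season']} {rec['year']} {int(100 * rec['q'])}% envelope: "
                f"[{env.lower_m:.0f}, {env.upper_m:.0f}) m AGL, width {env.width_m:.0f} m "
                f"({rec['n_scans']} scans)"
            )
        return "\n".join(lines)

    def plot_activity_curve(self, season: str, year: int, ax=None):
        """Fitted diel activity curve of one season–year."""
        for e in self.peak_estimates:
            if e.season == season and e.year == year and e.results is not None:
                return e.results.plot(ax=ax)
        raise ValueError(f"no fitted curve for {season} {year}")
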