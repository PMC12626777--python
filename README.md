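# skyflux

Quantifying how aerial migrants — chiefly nocturnally migrating birds —
use the lower atmosphere over a radar station, from weather-surveillance
radar vertical profiles: when activity peaks relative to sunset, how
much of it is nocturnal, and how thin an altitude band carries the bulk
of it.

Weather radars double as continental-scale biological sensors.  From
each radar acquisition the five lowest elevation sweeps (2.5–50 km
range) are assembled into a vertical profile of linear reflectivity
η (cm² km⁻³, a proxy for biological density) in thirty 100-m bins from
0 to 3000 m above ground level, with horizontal wind per bin retrieved
by a velocity-azimuth-display (VAD) least-squares fit of
v_r = (u sin φ + v cos φ) cos θ.  The **reflectivity traffic rate**

    RTR = Σᵢ ηᵢ · sᵢ · Δh     [cm² km⁻¹ h⁻¹]

(sᵢ the bin groundspeed in km/h, Δh = 0.1 km) is the total scattering
cross-section crossing a 1-km transect per hour, the transect taken
perpendicular to each bin's mean travel direction.  Scans are
regularized to a 5-min grid (nearest scan within < 1 h), slots with
more than 25% rain-classified voxels are removed, and sampling days
(20:00–19:59 UTC) are kept only when ≥ 90% of slots survive.  On this
series the package estimates, per station–season–year:

- **percent nocturnal activity**, at the seasonal level
  (100 · Σ nocturnal RTR / Σ all RTR; nocturnal ⇔ solar elevation < 0°),
  with the unweighted daily-mean percentage as a diagnostic;
- **peak timing**: a penalized cyclic-spline smooth (a GAM) of traffic
  rate on hours after sunset, fitted to the top quartile of days by
  mean activity, kept only when variance explained > 20% on ≥ 3 days;
  the peak is the curve's argmax on a 1-min grid;
- **flight-height envelopes**: the narrowest contiguous altitude band
  capturing 50% (and 75%) of passage during the peak window
  (peak ± 1 SD across years), summarized both as the mean of scan-level
  envelopes and as the envelope of pooled passage;
- **geographic trends**: OLS slopes of these metrics on station
  latitude/longitude, and paired/pooled t-tests between seasons.

A synthetic-data generator produces polar volumes and profile series
from a forward model with known ground truth (peak offset, altitude
envelope, percent nocturnal, wind profile), so the whole chain is
testable without any radar archive.

## Worked example

```python
import datetime as dt
from skyflux import SimulationConfig, simulate_profile_series, DielAirspaceModel

cfg = SimulationConfig(start_date=dt.date(2022, 4, 1), end_date=dt.date(2022, 4, 14),
                       nocturnal_peak_offset=4.0, seed=11)
series, truth = simulate_profile_series(cfg)
print("truth: peak", truth.true_peak_offset, "envelope", truth.true_envelope,
      "percent nocturnal", round(truth.true_percent_nocturnal, 1))

results = DielAirspaceModel(series).fit()
print(results.summary())
```

prints

```
truth: peak 4.0 envelope (200.0, 800.0) percent nocturnal 80.2
Diel airspace use — station SYNTH (35.333, -97.278)
  scans: 3378; grid slots: 4033; sampling days retained: 13/13

  spring 2022: 80.2% nocturnal (daily-mean diagnostic 80.2%, 13 days)
  spring 2022: peak 4.0 h after sunset (variance explained 99%, 4 days, ok)
  spring: mean peak 4.0 ± 0.0 h (1 year)
  spring 2022 50% envelope: [340, 879) m AGL, width 540 m (48 scans)
  spring 2022 75% envelope: [171, 1067) m AGL, width 896 m (48 scans)
```

Two weeks of simulated April scans at a mid-latitude station: the
fitted activity curve peaks 4.0 h after sunset (matching the
generator's pulse), 80.2% of passage is nocturnal (matching the
noise-free truth), and half of the migratory passage travels inside a
~500-m-thick band in the lowest kilometre.  The mean scan-level 50%
envelope ([340, 879) m) sits around the pooled-passage truth band
(200–800 m); scan-level noise widens individual envelopes relative to
the pooled summary, which lands within one bin of truth.
`results.diel_table`, `results.peak_table` and `results.envelope_table`
expose the same numbers as DataFrames, and
`results.plot_activity_curve("spring", 2022)` draws the fitted smooth.

The same pipeline runs from the shell:

```sh
skyflux --seed 11 --out-dir out run-all          # simulate + fit + CSV tables
skyflux --out-dir out diel out/series.vpts.csv   # analyses on an existing series
```

User-supplied profile series are read from a VPTS-style CSV (one row
per timestamp × height bin; see `skyflux.io.read_vpts`).

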