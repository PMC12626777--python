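# Methods

## Scope and data model

The package estimates diel airspace use at a single radar station from
a time series of vertical profiles.  Its in-memory backbone is the
`ProfileSeries`: one row per (scan timestamp, height bin), thirty
contiguous 100-m bins on [0, 3000) m above ground level, each carrying
linear reflectivity η (cm² km⁻³), VAD-retrieved wind (u, v), ground
speed, voxel support, and a scan-level rain fraction.  Precipitation
segmentation is treated as an input: every voxel arrives with a class
label (biology / rain / clutter / missing), produced upstream on real
data or by the simulator here.

## Profile assembly

Voxels from the five lowest elevation sweeps with slant range in
[2.5, 50] km are mapped to height with the standard
4/3-effective-Earth-radius propagation model,
h = √(r² + k_a² + 2 r k_a sin θ) − k_a, k_a = (4/3)·6371 km, and
binned by half-open 100-m intervals of beam-centre height; voxels at
or above 3000 m are discarded.  Heights are relative to the antenna
(station-relative AGL); tower height and terrain variation within the
50-km footprint are ignored.  Per bin, η is the arithmetic mean over
biology voxels with missing voxels counted as zero cross-section; rain
and clutter voxels never enter η but do enter the scan's rain fraction
(rain / all classified voxels).  Reflectivity factor converts to η as
η = 10³ (π⁵/λ⁴) |K_m|² 10^(dBZ/10) with |K_m|² = 0.93 and λ = 10.71 cm
(S-band) by default, so 0 dBZ ≈ 21.6 cm² km⁻³.  The wind per bin is
the two-parameter VAD least-squares fit (no vertical velocity, no
dealiasing — the simulator produces unaliased velocities); a bin needs
at least 20 velocity voxels with azimuthal diversity, otherwise it is
flagged missing.

With the WSR-88D's lowest five elevations (0.5–2.4°) the beam tops out
near 2250 m AGL at the 50-km range edge, so simulated volumes populate
roughly the lowest 23 bins; the remaining bins are missing rather than
zero.  The profile-series route of the simulator covers all 30 bins.

## Traffic rate and regularization

Per-bin traffic rate is η · s · Δh with s the scalar groundspeed in
km/h and Δh = 0.1 km; using the speed magnitude realizes the
direction-normal transect convention.  Bins with reflectivity but no
wind solution contribute zero and are flagged — no speed imputation,
keeping the estimator conservative.  Bin-mean η multiplies bin-mean
speed (voxel-level products are not formed).

Scans are placed on a 5-min grid by nearest-measurement assignment
with a strict < 60 min gap rule; a slot equidistant between two scans
takes the earlier one.  Linear interpolation between bracketing scans
is available (`method="linear"`) because the two conventions are both
defensible; nearest is the default.  Slots are dropped when the rain
fraction exceeds 0.25 (exactly 0.25 is kept).  Sampling days run 20:00
to 19:59 UTC (288 slots) and are retained when at least
⌈0.9 · 288⌉ = 260 slots are valid after both filters; rain filtering
happens before completeness counting.  Excluded slots enter neither
numerator nor denominator of any later summary.

## Solar geometry and seasons

Solar elevation comes from the NOAA solar-position equations
(declination, equation of time, hour angle), geometric — no refraction
— so sunset/sunrise are true 0° crossings, located by bisection to
≤ 1 s.  Packages that include refraction will place sunset a few
minutes later; differences at that scale are expected.  The nocturnal
phase requires elevation strictly below zero.  Hours after sunset
reference the most recent sunset and are continuous across midnight.
Polar day/night dates raise a flag and are excluded from
sunset-referenced analyses.  Seasons are inclusive calendar windows —
spring March 1–June 15, summer June 16–July 31, autumn August 1–
November 15 — containing 106, 45 and 106 complete sampling windows
respectively (one fewer than the calendar-day count, since a sampling
day needs both its start and end date inside the window).

## Diel partitioning

The headline metric is seasonal: 100 · Σ nocturnal RTR / Σ total RTR
over all valid slots of retained days.  It equals the passage-weighted
mean of daily percentages exactly, which is why it reflects the
migration system's dominant behaviour rather than giving a quiet day
the same weight as a 10,000-animal night; the unweighted daily mean is
emitted as a diagnostic.  Multi-station pooling is provided both ways
(summed passage, and mean of station percentages) since either
convention is seen in practice.

## Peak timing

Activity curves are penalized regressions of (by default) √RTR on
hours after sunset with a cyclic cubic spline basis, fitted to all
valid slots of the top-quartile days by daily mean activity (75th
percentile, linear interpolation; with fewer than four days all days
are used, flagged).  The square-root transform stabilises the variance
of heavily right-skewed traffic rates and matches how such profiles
are usually displayed; an identity-scale option exists.  The basis
(statsmodels `CyclicCubicSplines`) has dimension 40 with knots
anchored on the full [0, 24) cycle independent of sample coverage.
Forty basis functions are deliberately generous — the diel curve has a
sharp day/night transition at the sunset wrap that a ~20-dimension
basis visibly smears, biasing early peaks — and the smoothing penalty,
chosen by generalized cross-validation (GCV = n·RSS/(n − edf)²) over a
log-spaced grid of 17 penalty weights, controls the effective degrees
of freedom.  The penalized normal equations are solved directly; the
effective df is the trace of the hat matrix.  Variance explained is
1 − RSS/TSS on the fitting scale.  An estimate passes QC only when
variance explained exceeds 0.20 and at least three sampling days were
fitted.  The peak is the argmax of the fitted curve on a 1-min grid;
maxima within 1e-9 relative tolerance count as tied and the earliest
hour wins (a flat curve reports hour 0).  Across years, peaks
aggregate by arithmetic mean and sample SD (n − 1) on the linear hour
scale — not circular statistics, acceptable because peaks concentrate
far from the 0/24 wrap; a single year reports SD 0, flagged.

## Altitude envelopes

The envelope of a scan is the minimal contiguous window of bins whose
per-bin traffic rate sums to at least q (0.5 and 0.75) of the column
total, found by scanning widths upward on cumulative sums; ties break
toward the lowest starting height, and comparisons carry a 1e-9
relative guard against float summation error.  Envelopes are at bin
resolution (multiples of 100 m, no sub-bin interpolation) and assume a
unimodal band; non-contiguous mass sets are out of scope.  Scans enter
the envelope stage when they fall on the peak-fit's selected days with
hours after sunset inside peak ± 1 SD (SD across years; a zero SD
falls back to ±0.5 h, flagged; the window is not truncated at
sunrise).  Two summaries are produced: the mean of scan-level bounds
(with SDs), and the pooled envelope of passage summed across scans
first.

## Trends and season contrasts

Station-level metrics regress on latitude or longitude by univariate
OLS with two-sided t-tests (statsmodels).  Season comparisons use the
pooled-variance two-sample t-test (df = n₁ + n₂ − 2) or the paired
test; Welch is available by flag.  Paired differences with zero
variance are refused rather than reported as infinite t.

## The synthetic generator

The generator emulates the structure the pipeline must survive, not
radar engineering.  Activity factorises as
diel(t) × altitude(h) × noise: a Gaussian pulse in hours after sunset
(default peak offset 4 h, SD 2 h) active only while the sun is below
the horizon, plus a constant daylight baseline (insect-like) active
only while it is not — gating each component to its own phase keeps
"zero diurnal amplitude" meaning exactly 100% nocturnal.  Altitude
densities are truncated Gaussians on [0, 3000) m (nocturnal mode
600 m, spread 400 m; gamma available), binned to unit total mass.
Winds interpolate linearly between (height, u, v) nodes, defaulting to
a modest nocturnal-jet-like shear (≈4.5 m/s near the surface to
≈15 m/s at 3 km).  Scan cadence is irregular: mean 6 min with ±2 min
uniform jitter, rounded to whole seconds.  Noise is multiplicative
lognormal on η (σ = 0.2, mean one so unbiased) and additive Gaussian
(0.5 m/s) on radial velocity — magnitudes are package choices, exposed
in the config, as no empirical error model is imposed.  Rain episodes
stamp a voxel (or scan) fraction; overlaps combine by maximum.  All
randomness flows from one integer seed; identical configs give
bitwise-identical series.

Ground truth is computed from the noise-free forward model on the
5-min grid restricted to the complete 20:00–19:59 UTC sampling windows
of the simulated span — exactly the estimand the pipeline measures, so
recovery errors reflect the estimators, not span edge effects.  The
true envelope is the 50% band of the nocturnal per-bin traffic-rate
shape; the true percent nocturnal follows the phase of each grid slot.
`diurnal_amplitude_for_nocturnality` inverts the closed-form relation
between the diurnal amplitude and the seasonal percent to calibrate a
simulation to a target nocturnality.

What the generator does not emulate: NEXRAD Level II encodings,
beam blockage, dual-polarization moments, velocity aliasing, terrain,
spatially heterogeneous migration, or classifier errors in the
biology/rain labels.  Passing tests therefore demonstrate that the
estimators recover known structure under realistic sampling, noise and
contamination — not that any real archive would yield particular
values.

## Problem sizes and numerical choices

Simulation-backed tests use 8-to-30-day single-station runs
(~2,400–7,200 scans) and a 40-station, 8-day ensemble for the
latitudinal-gradient check; the acceptance script uses the same sizes
and finishes in well under a minute.  Degenerate inputs are flagged
rather than guessed at: all-zero profiles have no envelope, zero total
passage has no percentage, underdetermined VAD bins and singular
smooths are missing, and out-of-span rain episodes warn and pass
through.  Known limitations: linear (not circular) SD of peak hours;
station-relative heights; envelopes at bin resolution; no velocity
dealiasing; the daily-mean diel metric excludes zero-passage days.
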