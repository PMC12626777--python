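"""The synthetic generator: determinism, conservation, ground truth,
polar-volume geometry, rain injection, and the simulator round trip."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from skyflux.profiles import VoxelClass, build_profile
from skyflux.series import N_BINS
from skyflux.simulate import (
    RainEpisode,
    SimulationConfig,
    _diel_weights,
    _model_eta,
    inject_rain,
    simulate_polar_volume,
    simulate_profile_series,
)


def test_identical_seed_bitwise_identical(ten_day_config):
    s1, t1 = simulate_profile_series(ten_day_config)
    s2, t2 = simulate_profile_series(ten_day_config)
    pd.testing.assert_frame_equal(s1.df, s2.df)
    assert t1.true_percent_nocturnal == t2.true_percent_nocturnal


def test_different_seed_differs(ten_day_config):
    s1, _ = simulate_profile_series(ten_day_config)
    s2, _ = simulate_profile_series(replace(ten_day_config, seed=43))
    assert not s1.df["eta"].equals(s2.df["eta"])


def test_noise_free_conservation(ten_day_config):
    # sum of per-bin eta equals the diel curve times total altitude mass (=1)
    cfg = replace(ten_day_config, noise_sd=0.0)
    series, _ = simulate_profile_series(cfg)
    times = series.timestamps
    w_noct, w_diur = _diel_weights(cfg, times)
    col_sum = series.df.groupby("datetime")["eta"].sum().to_numpy()
    assert np.allclose(col_sum, w_noct + w_diur, rtol=1e-9)


def test_scan_cadence_in_configured_band(ten_day_series):
    series, _ = ten_day_series
    gaps = np.diff(series.timestamps.asi8) / 60e9
    # mean 6 +/- jitter 2, with second-rounding of scan clocks
    assert gaps.min() >= 4.0 - 1 / 60 and gaps.max() <= 8.0 + 1 / 60


def test_pure_nocturnal_truth_is_100(ten_day_config):
    cfg = replace(ten_day_config, diurnal_amplitude=0.0)
    _, truth = simulate_profile_series(cfg)
    assert truth.true_percent_nocturnal == pytest.approx(100.0, abs=1e-9)


def test_all_zero_amplitudes_flagged(ten_day_config):
    cfg = replace(ten_day_config, diurnal_amplitude=0.0, nocturnal_amplitude=0.0)
    series, truth = simulate_profile_series(cfg)
    assert np.all(series.df["eta"] == 0.0)
    assert truth.true_envelope is None
    assert np.isnan(truth.true_percent_nocturnal)
    assert truth.flags


def test_invalid_configs_rejected():
    with pytest.raises(ValueError, match="date range"):
        SimulationConfig(start_date=dt.date(2022, 5, 1), end_date=dt.date(2022, 4, 1))
    with pytest.raises(ValueError, match="amplitude"):
        SimulationConfig(nocturnal_amplitude=-1.0)
    with pytest.raises(ValueError, match="pulse_sd"):
        SimulationConfig(nocturnal_pulse_sd=0.0)


class TestInjectRain:
    def test_single_episode_stamps_fraction(self, ten_day_series):
        series, _ = ten_day_series
        t0 = series.timestamps[10]
        out = inject_rain(series, [RainEpisode(t0, t0, 0.30)])
        scan = out.df[out.df["datetime"] == t0]
        assert (scan["rain_fraction"] == 0.30).all()
        assert (out.df.loc[out.df["datetime"] != t0, "rain_fraction"] == 0.0).all()

    def test_no_episodes_identity(self, ten_day_series):
        series, _ = ten_day_series
        out = inject_rain(series, [])
        pd.testing.assert_frame_equal(out.df, series.df)

    def test_overlapping_episodes_take_maximum(self, ten_day_series):
        series, _ = ten_day_series
        t0, t1 = series.timestamps[0], series.timestamps[20]
        out = inject_rain(
            series, [RainEpisode(t0, t1, 0.2), RainEpisode(t0, t1, 0.15)]
        )
        hit = out.df["datetime"] <= t1
        assert (out.df.loc[hit, "rain_fraction"] == 0.2).all()

    def test_out_of_span_episode_warned_and_ignored(self, ten_day_series):
        series, _ = ten_day_series
        with pytest.warns(UserWarning, match="outside series span"):
            out = inject_rain(series, [RainEpisode("2021-01-01", "2021-01-02", 0.9)])
        assert (out.df["rain_fraction"] == 0.0).all()


class TestPolarVolume:
    def test_radial_velocity_projection(self, ten_day_config):
        # constant wind (10, 0): +10 m/s toward azimuth 90, -10 at 270
        cfg = replace(
            ten_day_config,
            wind_profile=((0.0, 10.0, 0.0), (3000.0, 10.0, 0.0)),
            velocity_noise_sd=0.0,
            noise_sd=0.0,
        )
        vol = simulate_polar_volume(cfg, pd.Timestamp("2022-04-02 03:00"))
        sw = vol.sweeps[0]
        ce = np.cos(np.deg2rad(sw.elevation_deg))
        i90 = int(np.flatnonzero(sw.azimuth_deg == 90.0)[0])
        i270 = int(np.flatnonzero(sw.azimuth_deg == 270.0)[0])
        assert np.allclose(sw.vrad[i90], 10.0 * ce)
        assert np.allclose(sw.vrad[i270], -10.0 * ce)

    def test_zero_wind_zero_velocity(self, ten_day_config):
        cfg = replace(
            ten_day_config,
            wind_profile=((0.0, 0.0, 0.0), (3000.0, 0.0, 0.0)),
            velocity_noise_sd=0.0,
        )
        vol = simulate_polar_volume(cfg, pd.Timestamp("2022-04-02 03:00"))
        assert all(np.allclose(sw.vrad, 0.0) for sw in vol.sweeps)

    def test_time_outside_range_rejected(self, ten_day_config):
        with pytest.raises(ValueError, match="outside"):
            simulate_polar_volume(ten_day_config, pd.Timestamp("2023-01-01"))

    def test_rain_episode_labels_voxels(self, ten_day_config):
        t = pd.Timestamp("2022-04-02 03:00")
        cfg = replace(ten_day_config, rain_episodes=(RainEpisode(t, t, 0.5),))
        vol = simulate_polar_volume(cfg, t)
        frac = np.mean(
            [np.mean(sw.voxel_class == int(VoxelClass.RAIN)) for sw in vol.sweeps]
        )
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_round_trip_recovers_profile(self, ten_day_config):
        """Noise-free volume -> build_profile recovers the model's
        per-bin eta (within 5%) and wind (within 0.1 m/s)."""
        cfg = replace(ten_day_config, noise_sd=0.0, velocity_noise_sd=0.0)
        t = pd.Timestamp("2022-04-02 03:00")  # nocturnal, strong pulse
        vol = simulate_polar_volume(cfg, t)
        prof = build_profile(vol)
        truth_eta = _model_eta(cfg, pd.DatetimeIndex([t]))[0]
        covered = prof.n_voxels > 0
        # the five lowest sweeps reach ~2250 m AGL at the 50-km range edge
        assert covered.sum() >= 20
        ok = covered & (truth_eta > 1e-12)
        assert np.allclose(prof.eta[ok], truth_eta[ok], rtol=0.05)
        from skyflux.simulate import _bin_centers, _wind_at

        u_true, v_true = _wind_at(cfg, _bin_centers())
        fit = np.isfinite(prof.u)
        assert np.nanmax(np.abs(prof.u[fit] - u_true[fit])) < 0.1
        assert np.nanmax(np.abs(prof.v[fit] - v_true[fit])) < 0.1
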