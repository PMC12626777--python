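"""Beam geometry, reflectivity conversion, VAD retrieval, profile assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from skyflux.profiles import (
    PolarVolume,
    ProfileOptions,
    Sweep,
    VoxelClass,
    beam_height,
    build_profile,
    dbz_to_eta,
    eta_to_dbz,
    vad_fit,
)
from skyflux.series import N_BINS, Station


class TestBeamHeight:
    def test_zero_range(self):
        assert beam_height(0.0, 0.5) == pytest.approx(0.0)

    def test_vertical_beam_collapses_to_range(self):
        assert beam_height(10.0, 90.0) == pytest.approx(10_000.0, rel=1e-9)

    def test_standard_low_sweep(self):
        # 4/3-Earth formula at the far edge of the analysis window
        assert beam_height(50.0, 0.5) == pytest.approx(583.5, abs=0.5)

    def test_strictly_increasing_in_range_and_elevation(self):
        r = np.linspace(0.1, 60, 200)
        h = beam_height(r, 0.5)
        assert (np.diff(h) > 0).all()
        elevs = np.linspace(0.0, 10.0, 50)
        h2 = np.array([beam_height(30.0, e) for e in elevs])
        assert (np.diff(h2) > 0).all()


class TestReflectivityConversion:
    def test_missing_maps_to_zero(self):
        assert dbz_to_eta(np.nan) == 0.0
        assert dbz_to_eta(-np.inf) == 0.0

    def test_ten_db_is_factor_ten(self):
        assert dbz_to_eta(15.0) / dbz_to_eta(5.0) == pytest.approx(10.0, rel=1e-12)

    def test_sband_constant(self):
        # 0 dBZ at the 10.71 cm S-band wavelength
        assert dbz_to_eta(0.0, 10.71) == pytest.approx(21.6, abs=0.05)

    @given(st.floats(min_value=-30, max_value=60))
    @settings(max_examples=50, derandomize=True)
    def test_round_trip(self, dbz):
        assert eta_to_dbz(dbz_to_eta(dbz)) == pytest.approx(dbz, rel=1e-12, abs=1e-12)


def normal_equations_wind(az_deg, elev_deg, vrad):
    """Independent oracle: explicit 2x2 normal-equations solve."""
    az = np.deg2rad(np.asarray(az_deg))
    ce = np.cos(np.deg2rad(np.asarray(elev_deg)))
    a1, a2 = np.sin(az) * ce, np.cos(az) * ce
    A = np.array([[np.sum(a1 * a1), np.sum(a1 * a2)], [np.sum(a1 * a2), np.sum(a2 * a2)]])
    b = np.array([np.sum(a1 * vrad), np.sum(a2 * vrad)])
    return np.linalg.solve(A, b)


class TestVAD:
    def test_exact_recovery_noise_free(self):
        az = np.arange(360.0)
        vr = (10.0 * np.sin(np.deg2rad(az))) * np.cos(np.deg2rad(0.5))
        u, v, speed, direction, rmse, n = vad_fit(az, 0.5, vr)
        assert u == pytest.approx(10.0, abs=1e-9)
        assert v == pytest.approx(0.0, abs=1e-9)
        assert direction == pytest.approx(90.0, abs=1e-6)
        assert rmse == pytest.approx(0.0, abs=1e-9)

    def test_zero_velocities(self):
        az = np.arange(360.0)
        u, v, speed, direction, rmse, n = vad_fit(az, 0.5, np.zeros(360))
        assert speed == 0.0 and rmse == 0.0

    def test_matches_normal_equations_oracle_under_noise(self):
        rng = np.random.default_rng(7)
        az = np.arange(360.0)
        elev = 1.3
        true_u, true_v = 6.0, -3.5
        vr = (true_u * np.sin(np.deg2rad(az)) + true_v * np.cos(np.deg2rad(az))) * np.cos(
            np.deg2rad(elev)
        ) + rng.normal(0, 0.5, 360)
        u, v, *_ = vad_fit(az, elev, vr)
        ou, ov = normal_equations_wind(az, elev, vr)
        assert u == pytest.approx(ou, abs=1e-9)
        assert v == pytest.approx(ov, abs=1e-9)
        assert abs(u - true_u) < 0.1 and abs(v - true_v) < 0.1

    def test_underdetermined_flagged(self):
        # all azimuths identical: rank deficient
        az = np.full(50, 123.0)
        out = vad_fit(az, 0.5, np.ones(50))
        assert np.isnan(out[0]) and out[5] == 50
        # below the minimum voxel count
        out = vad_fit(np.arange(10.0), 0.5, np.ones(10))
        assert np.isnan(out[0]) and out[5] == 10


def _single_sweep_volume(elev, ranges, dbz_row, vrad_row=None, cls_row=None, station=None):
    n_az, n_rg = 360, len(ranges)
    az = np.arange(float(n_az))
    dbz = np.tile(dbz_row, (n_az, 1))
    vrad = np.tile(vrad_row if vrad_row is not None else np.zeros(n_rg), (n_az, 1))
    cls = np.tile(
        cls_row if cls_row is not None else np.full(n_rg, int(VoxelClass.BIOLOGY)), (n_az, 1)
    )
    sweep = Sweep(elev, az, np.asarray(ranges, float), dbz, vrad, cls.astype(np.int8))
    return PolarVolume(station or Station("T", 35.0, -97.0), pd.Timestamp("2022-04-01"), [sweep])


class TestBuildProfile:
    def test_thirty_bins_covering_0_3000(self):
        vol = _single_sweep_volume(0.5, np.arange(2.5, 50.5, 0.5), np.zeros(96))
        with pytest.warns(UserWarning):
            prof = build_profile(vol)
        assert prof.eta.shape == (N_BINS,)
        assert prof.heights[0] == 0.0 and prof.heights[-1] == 2900.0
        assert np.all(np.diff(prof.heights) == 100.0)

    def test_height_localised_activity_lands_in_matching_bins(self):
        # put reflectivity only in gates whose beam height is in [400, 600)
        ranges = np.arange(2.5, 50.5, 0.5)
        h = beam_height(ranges, 0.5)
        sel = (h >= 400) & (h < 600)
        dbz_row = np.where(sel, 10.0, np.nan)
        vol = _single_sweep_volume(0.5, ranges, dbz_row)
        with pytest.warns(UserWarning):
            prof = build_profile(vol)
        hot = np.flatnonzero(np.nan_to_num(prof.eta) > 0)
        assert set(prof.heights[hot]) == {400.0, 500.0}

    def test_all_rain_scan(self):
        ranges = np.arange(2.5, 50.5, 0.5)
        cls_row = np.full(len(ranges), int(VoxelClass.RAIN))
        vol = _single_sweep_volume(0.5, ranges, np.full(len(ranges), 10.0), cls_row=cls_row)
        with pytest.warns(UserWarning):
            prof = build_profile(vol)
        assert prof.rain_fraction == 1.0
        assert np.all(np.isnan(prof.eta))
        assert "all_bins_missing" in prof.flags

    def test_range_window_and_bin_partition(self):
        ranges = np.arange(0.5, 60.5, 0.5)  # includes gates outside 2.5-50 km
        vol = _single_sweep_volume(0.5, ranges, np.zeros(len(ranges)))
        with pytest.warns(UserWarning):
            prof = build_profile(vol)
        in_window = (ranges >= 2.5) & (ranges <= 50.0)
        below = beam_height(ranges[in_window], 0.5) < 3000
        assert prof.n_voxels.sum() == 360 * int(below.sum())

    def test_out_of_range_volume_flagged(self):
        vol = _single_sweep_volume(0.5, np.array([60.0, 70.0]), np.zeros(2))
        with pytest.warns(UserWarning):
            prof = build_profile(vol)
        assert "no_voxels_in_range_window" in prof.flags
        assert np.all(np.isnan(prof.eta))
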