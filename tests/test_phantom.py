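"""Synthetic phantom: geometry, angular laws, signal generation."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from relaxaniso.phantom import (
    PARAMETER_KINDS,
    AcquisitionSchedule,
    PhantomSpec,
    dipolar_factor,
    effective_rate,
    fibre_angle_profile,
    generate_plm_maps,
    generate_series,
    magic_angle_deg,
    true_rate,
)
from relaxaniso.plm import circular_orientation_mean


class TestFibreAngleProfile:
    def test_surface_is_parallel_to_surface(self, spec):
        assert fibre_angle_profile(0.0, spec) == pytest.approx(90.0)

    def test_deep_zone_is_radial(self, spec):
        assert fibre_angle_profile(1.0, spec) == pytest.approx(0.0)
        # radial zone spans depth >= 0.3 in the default geometry
        assert fibre_angle_profile(0.5, spec) == pytest.approx(0.0)
        assert fibre_angle_profile(0.3, spec) == pytest.approx(0.0)

    def test_monotone_and_continuous_through_tz(self, spec):
        d = np.linspace(0.0, 1.0, 400)
        a = fibre_angle_profile(d, spec)
        assert np.all(np.diff(a) <= 1e-12)  # non-increasing
        assert np.max(np.abs(np.diff(a))) < 2.0  # no jumps

    def test_depth_outside_unit_interval_rejected(self, spec):
        with pytest.raises(ValueError):
            fibre_angle_profile(-0.1, spec)
        with pytest.raises(ValueError):
            fibre_angle_profile(1.2, spec)


class TestDipolarFactor:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 2.0), (90.0, -1.0), (180.0, 2.0), (-54.7356, 0.0)],
    )
    def test_known_angles(self, theta, expected):
        assert dipolar_factor(theta) == pytest.approx(expected, abs=1e-3)

    def test_magic_angle_root(self):
        ma = magic_angle_deg()
        assert abs(dipolar_factor(ma)) < 1e-10
        assert ma == pytest.approx(54.7356, abs=1e-3)

    def test_symmetry_and_period(self):
        th = np.linspace(-180, 180, 121)
        assert dipolar_factor(th) == pytest.approx(dipolar_factor(-th))
        assert dipolar_factor(th) == pytest.approx(dipolar_factor(th + 180.0))


class TestTrueRate:
    def test_magic_angle_nulls_dipolar_term(self, spec):
        # fibre at depth 1 is 0 deg; orient the sample at the magic angle
        ma = magic_angle_deg()
        rate = true_rate(1.0, ma, "T2", spec)
        assert rate == pytest.approx(spec.relax_params["T2"].r_iso, rel=1e-6)

    def test_t1_is_orientation_independent(self, spec):
        assert true_rate(0.5, 0.0, "T1", spec) == true_rate(0.5, 90.0, "T1", spec)

    def test_theta_zero_rate_is_riso_plus_cdip(self):
        params = {"T2": dataclasses.replace(PhantomSpec().relax_params["T2"],
                                            r_iso=10.0, c_dip=40.0)}
        spec = dataclasses.replace(PhantomSpec(), relax_params={**PhantomSpec().relax_params, **params})
        # depth 1.0 -> fibre 0 deg; orientation 0 -> theta_eff = 0
        assert true_rate(1.0, 0.0, "T2", spec) == pytest.approx(50.0)

    def test_unknown_kind_rejected(self, spec):
        with pytest.raises(ValueError):
            true_rate(0.5, 0.0, "T3", spec)

    def test_effective_rate_reduces_to_point_law_without_dispersion(self):
        spec = dataclasses.replace(PhantomSpec(), dispersion_deg=(0.0, 0.0, 0.0))
        d = np.linspace(0, 1, 17)
        assert effective_rate(d, 30.0, "T2", spec) == pytest.approx(
            true_rate(d, 30.0, "T2", spec), rel=1e-9
        )


class TestSchedules:
    def test_prep_times_strictly_increasing_required(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule("T2", (10.0, 10.0, 20.0, 40.0))

    def test_minimum_points_required(self):
        with pytest.raises(ValueError):
            AcquisitionSchedule("T2", (10.0, 20.0, 40.0))

    def test_default_schedules_cover_all_kinds(self, schedules):
        assert set(schedules) == set(PARAMETER_KINDS)
        assert schedules["RAFF2"].has_inversion_pair
        assert schedules["RAFF2"].pulse_duration_ms == 9.0
        assert schedules["AdT2rho"].pulse_duration_ms == 4.5


class TestGenerateSeries:
    def test_noiseless_signal_follows_model(self, noiseless_spec, schedules):
        series = generate_series(noiseless_spec, schedules["T2"], 90.0)
        t = np.asarray(series.schedule.prep_times_ms)
        depth = noiseless_spec.depth_of_rows()
        rate_ms = effective_rate(depth, 90.0, "T2", noiseless_spec) / 1000.0
        expected = noiseless_spec.s0 * np.exp(-t[:, None] * rate_ms[None, :])
        got = series.data[:, noiseless_spec.cartilage_rows, 7]
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_seeded_determinism_bit_identical(self, spec, schedules):
        a = generate_series(spec, schedules["RAFF2"], 30.0)
        b = generate_series(spec, schedules["RAFF2"], 30.0)
        assert a.data.tobytes() == b.data.tobytes()
        assert a.data_inverted.tobytes() == b.data_inverted.tobytes()

    def test_different_seeds_differ(self, spec, schedules):
        other = spec.with_seed(99)
        a = generate_series(spec, schedules["T2"], 30.0)
        b = generate_series(other, schedules["T2"], 30.0)
        assert a.data.tobytes() != b.data.tobytes()

    def test_measured_snr_matches_requested(self, schedules):
        spec = PhantomSpec(seed=3, snr=50.0)
        series = generate_series(spec, schedules["T2"], 45.0)
        fg = series.data[0][series.mask].mean()
        bg_sigma = series.data[:, series.background_roi].std() / np.sqrt((4 - np.pi) / 2)
        measured = fg / bg_sigma
        assert measured == pytest.approx(50.0, rel=0.2)

    def test_mask_and_background_disjoint(self, spec, schedules):
        series = generate_series(spec, schedules["T1"], 0.0)
        assert not np.any(series.mask & series.background_roi)
        assert series.background_roi.sum() >= 50

    def test_t1_series_orientation_independent_up_to_noise(self, spec, schedules):
        """Pixel distributions at 0 and 90 deg are statistically identical."""
        a = generate_series(spec, schedules["T1"], 0.0)
        b = generate_series(spec.with_seed(17), schedules["T1"], 90.0)
        rng = np.random.default_rng(0)
        pix_a = a.data[0][a.mask]
        pix_b = b.data[0][b.mask]
        sel = rng.choice(min(pix_a.size, pix_b.size), 500, replace=False)
        ks = stats.ks_2samp(pix_a[sel], pix_b[sel])
        assert ks.pvalue > 0.01


class TestGeneratePLMMaps:
    def test_zero_dispersion_map_is_replicated_depth_profile(self):
        spec = dataclasses.replace(PhantomSpec(seed=2), dispersion_deg=(0.0, 0.0, 0.0))
        maps = generate_plm_maps(spec)
        depth = spec.depth_of_rows()
        expected = np.mod(fibre_angle_profile(depth, spec), 180.0)
        cart = maps.orientation[spec.cartilage_rows, :]
        np.testing.assert_allclose(
            cart, np.broadcast_to(expected[:, None], cart.shape), atol=1e-12
        )

    def test_orientation_wrapped(self, spec):
        maps = generate_plm_maps(spec)
        assert maps.orientation.min() >= 0.0
        assert maps.orientation.max() < 180.0

    def test_rz_circular_spread_within_configured_dispersion(self, spec):
        maps = generate_plm_maps(spec)
        depth = spec.depth_of_rows()
        rz_rows = np.flatnonzero(depth >= spec.rz_start) + spec.surface_row
        angles = maps.orientation[rz_rows, :].ravel()
        # circular std about the circular mean, 180-deg period
        mean = circular_orientation_mean(angles)
        dev = (angles - mean + 90.0) % 180.0 - 90.0
        assert dev.std() <= spec.dispersion_deg[2] + 1.0

    def test_sz_rz_mean_orientation_gap_configurable(self):
        spec75 = dataclasses.replace(
            PhantomSpec(seed=4), sz_orientation_deg=75.0, dispersion_deg=(0.0, 0.0, 0.0)
        )
        maps = generate_plm_maps(spec75)
        depth = spec75.depth_of_rows()
        sz = maps.orientation[spec75.surface_row + np.flatnonzero(depth < spec75.sz_end), :]
        rz = maps.orientation[spec75.surface_row + np.flatnonzero(depth >= spec75.rz_start), :]
        gap = circular_orientation_mean(sz.ravel()) - circular_orientation_mean(rz.ravel())
        assert gap == pytest.approx(75.0, abs=1.0)

    def test_retardation_nonnegative_and_deterministic(self, spec):
        a = generate_plm_maps(spec)
        b = generate_plm_maps(spec)
        assert np.all(a.retardation >= 0)
        assert a.orientation.tobytes() == b.orientation.tobytes()
        assert a.retardation.tobytes() == b.retardation.tobytes()


def test_spec_invariants_enforced():
    with pytest.raises(ValueError):
        PhantomSpec(snr=-1.0)
    with pytest.raises(ValueError):
        PhantomSpec(sz_end=0.5, rz_start=0.3)
    with pytest.raises(ValueError):
        PhantomSpec(surface_row=40, cartilage_depth_px=48)
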