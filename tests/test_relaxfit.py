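"""Relaxation fitting: exact recovery, noise handling, oracle equivalence."""

import numpy as np
import pytest

from relaxaniso.phantom import generate_series
from relaxaniso.relaxfit import (
    FitModelSpec,
    correct_noise_floor,
    estimate_noise_sigma,
    fit_exp_baseline,
    fit_inversion_recovery,
    fit_map,
    fit_monoexp_noisefloor,
    fit_raff_steadystate,
    model_for_kind,
)

TE_SE = np.array([10.0, 20.0, 40.0, 80.0, 100.0, 128.0])
T_SL = np.array([0.0, 24.0, 48.0, 96.0, 192.0])
TI = np.array([200.0, 500.0, 800.0, 1100.0, 1400.0, 3000.0])
N_RAFF = np.array([0, 2, 4, 6, 8])


# --------------------------------------------------------------------------
# noise sigma
# --------------------------------------------------------------------------


class TestNoiseSigma:
    def test_zero_background_gives_zero_sigma(self, noiseless_spec, schedules):
        series = generate_series(noiseless_spec, schedules["T2"], 0.0)
        assert estimate_noise_sigma(series) == 0.0

    def test_rayleigh_monte_carlo(self):
        rng = np.random.default_rng(0)
        sigma = 10.0
        vals = np.hypot(rng.normal(0, sigma, 10_000), rng.normal(0, sigma, 10_000))
        est = vals.mean() / np.sqrt(np.pi / 2)
        assert est == pytest.approx(sigma, abs=0.5)

    def test_small_background_rejected(self, spec, schedules):
        series = generate_series(spec, schedules["T2"], 0.0)
        series.background_roi = np.zeros_like(series.background_roi)
        with pytest.raises(ValueError):
            estimate_noise_sigma(series)

    def test_noise_floor_correction_idempotent_on_noiseless(self):
        s = 1000.0 * np.exp(-TE_SE / 50.0)
        np.testing.assert_array_equal(correct_noise_floor(s, 0.0), s)


# --------------------------------------------------------------------------
# exact recovery on noiseless curves
# --------------------------------------------------------------------------


class TestExactRecovery:
    def test_monoexp(self):
        y = 1000.0 * np.exp(-TE_SE / 50.0)
        r = fit_monoexp_noisefloor(TE_SE, y, 0.0)
        assert r.converged
        assert r.time_ms == pytest.approx(50.0, rel=1e-6)
        assert r.amplitude == pytest.approx(1000.0, rel=1e-6)

    def test_monoexp_floor_subtraction_inverts_construction(self):
        sigma = 30.0
        y = np.sqrt((1000.0 * np.exp(-TE_SE / 50.0)) ** 2 + sigma**2)
        r = fit_monoexp_noisefloor(TE_SE, y, sigma)
        assert r.time_ms == pytest.approx(50.0, rel=1e-6)

    def test_exp_baseline(self):
        y = 800.0 * np.exp(-T_SL / 60.0) + 50.0
        r = fit_exp_baseline(T_SL, y)
        assert r.converged
        assert (r.amplitude, r.baseline, r.time_ms) == (
            pytest.approx(800.0, rel=1e-6),
            pytest.approx(50.0, rel=1e-6),
            pytest.approx(60.0, rel=1e-6),
        )

    def test_exp_baseline_nests_monoexp(self):
        y = 900.0 * np.exp(-T_SL[1:] / 45.0)
        rb = fit_exp_baseline(T_SL[1:], y)
        rm = fit_monoexp_noisefloor(T_SL[1:], y, 0.0)
        assert rb.time_ms == pytest.approx(rm.time_ms, rel=1e-6)

    def test_inversion_recovery(self):
        y = 1000.0 * np.abs(1.0 - 2.0 * np.exp(-TI / 1400.0))
        r = fit_inversion_recovery(TI, y)
        assert r.converged
        assert r.time_ms == pytest.approx(1400.0, rel=1e-6)
        assert r.amplitude == pytest.approx(1000.0, rel=1e-6)

    def test_inversion_recovery_scale_invariant(self):
        y = 1000.0 * np.abs(1.0 - 2.0 * 0.9 * np.exp(-TI / 900.0))
        t1 = fit_inversion_recovery(TI, y).time_ms
        t1k = fit_inversion_recovery(TI, 7.3 * y).time_ms
        assert t1k == pytest.approx(t1, rel=1e-9)

    def test_raff_pair_with_folded_inverted_curve(self):
        t = N_RAFF * 9.0
        ss, s0p, s0i, T = 200.0, 1000.0, -600.0, 70.0
        yp = ss + (s0p - ss) * np.exp(-t / T)
        yi = np.abs(ss + (s0i - ss) * np.exp(-t / T))
        r = fit_raff_steadystate(N_RAFF, yp, yi, 9.0)
        assert r.converged
        assert r.time_ms == pytest.approx(70.0, rel=1e-6)
        assert r.steady_state == pytest.approx(200.0, rel=1e-6)
        assert r.amplitude_inverted == pytest.approx(-600.0, rel=1e-6)


# --------------------------------------------------------------------------
# degenerate and invalid inputs
# --------------------------------------------------------------------------


class TestDegenerateInputs:
    def test_constant_signal_flagged(self):
        r = fit_monoexp_noisefloor(TE_SE, np.full(6, 120.0), 0.0)
        assert not r.converged

    def test_all_zero_after_floor_flagged(self):
        r = fit_monoexp_noisefloor(TE_SE, np.full(6, 5.0), 50.0)
        assert not r.converged

    def test_negative_prep_time_rejected(self):
        with pytest.raises(ValueError):
            fit_monoexp_noisefloor(np.array([-1.0, 10, 20, 40]), np.ones(4), 0.0)

    def test_constant_exp_baseline_flagged(self):
        r = fit_exp_baseline(T_SL, np.full(5, 77.0))
        assert not r.converged

    def test_raff_mismatched_axes_rejected(self):
        with pytest.raises(ValueError):
            fit_raff_steadystate(N_RAFF, np.ones(5), np.ones(4), 9.0)

    def test_raff_constant_pair_flagged(self):
        r = fit_raff_steadystate(N_RAFF, np.full(5, 300.0), np.full(5, 300.0), 9.0)
        assert not r.converged

    def test_invalid_model_spec(self):
        with pytest.raises(ValueError):
            FitModelSpec(model="biexp")
        with pytest.raises(ValueError):
            FitModelSpec(t_bounds_ms=(0.0, 100.0))


# --------------------------------------------------------------------------
# independent oracle: dense log-grid search with linear subproblems
# --------------------------------------------------------------------------

GRID = np.geomspace(1.0, 10_000.0, 241)  # 3 decades, 80 steps/decade
GRID_STEP = np.log(GRID[1] / GRID[0])


def _grid_monoexp(t, y):
    best = (np.inf, None)
    for T in GRID:
        e = np.exp(-t / T)
        s0 = max((y * e).sum() / (e * e).sum(), 0.0)
        rss = ((y - s0 * e) ** 2).sum()
        if rss < best[0]:
            best = (rss, T)
    return best[1]


def _grid_exp_baseline(t, y):
    best = (np.inf, None)
    for T in GRID:
        e = np.exp(-t / T)
        X = np.stack([e, np.ones_like(e)], axis=1)
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = ((y - X @ coef) ** 2).sum()
        if rss < best[0]:
            best = (rss, T)
    return best[1]


def _grid_ir(t, y):
    best = (np.inf, None)
    for T in GRID:
        for f in np.linspace(0.5, 1.0, 26):
            m = np.abs(1.0 - 2.0 * f * np.exp(-t / T))
            denom = (m * m).sum()
            if denom == 0:
                continue
            s0 = (y * m).sum() / denom
            rss = ((y - s0 * m) ** 2).sum()
            if rss < best[0]:
                best = (rss, T)
    return best[1]


def _grid_raff(t, yp, yi):
    # same hypothesis space as the fitter: every monotone sign-restoration
    # prefix of the magnitude inverted curve; linear in (SS, S0p, S0i)
    best = (np.inf, None)
    m = t.size
    for k in range(m + 1):
        signs = np.where(np.arange(m) < k, -1.0, 1.0)
        yy = np.concatenate([yp, yi * signs])
        for T in GRID:
            e = np.exp(-t / T)
            zero = np.zeros_like(e)
            Xp = np.stack([1.0 - e, e, zero], axis=1)
            Xi = np.stack([1.0 - e, zero, e], axis=1)
            X = np.concatenate([Xp, Xi])
            coef, *_ = np.linalg.lstsq(X, yy, rcond=None)
            rss = ((yy - X @ coef) ** 2).sum()
            if rss < best[0]:
                best = (rss, T)
    return best[1]


class TestGridOracleEquivalence:
    """The LM optimum agrees with a dense log-grid search on noisy curves."""

    def test_monoexp(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            T = rng.uniform(15.0, 120.0)
            y = 1000.0 * np.exp(-TE_SE / T) + rng.normal(0, 20.0, TE_SE.size)
            y = np.clip(y, 0.0, None)
            fit = fit_monoexp_noisefloor(TE_SE, y, 0.0)
            oracle = _grid_monoexp(TE_SE, y)
            assert abs(np.log(fit.time_ms / oracle)) <= GRID_STEP

    def test_exp_baseline(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            T = rng.uniform(30.0, 120.0)
            y = 900.0 * np.exp(-T_SL / T) + 60.0 + rng.normal(0, 20.0, T_SL.size)
            fit = fit_exp_baseline(T_SL, y)
            oracle = _grid_exp_baseline(T_SL, y)
            assert abs(np.log(fit.time_ms / oracle)) <= GRID_STEP

    def test_inversion_recovery(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            T1 = rng.uniform(700.0, 2200.0)
            f = rng.uniform(0.85, 1.0)
            y = 1000.0 * np.abs(1 - 2 * f * np.exp(-TI / T1))
            y = np.abs(y + rng.normal(0, 25.0, TI.size))
            fit = fit_inversion_recovery(TI, y)
            oracle = _grid_ir(TI, y)
            assert abs(np.log(fit.time_ms / oracle)) <= GRID_STEP

    def test_raff(self):
        rng = np.random.default_rng(14)
        t = N_RAFF * 9.0
        for _ in range(20):
            T = rng.uniform(40.0, 110.0)
            ss = rng.uniform(150.0, 300.0)
            yp = ss + (1000.0 - ss) * np.exp(-t / T) + rng.normal(0, 18.0, t.size)
            # unfolded inverted curve keeps the oracle's linear subproblem exact
            yi = ss + (450.0 - ss) * np.exp(-t / T) + rng.normal(0, 18.0, t.size)
            fit = fit_raff_steadystate(N_RAFF, yp, yi, 9.0)
            oracle = _grid_raff(t, yp, yi)
            assert abs(np.log(fit.time_ms / oracle)) <= GRID_STEP


# --------------------------------------------------------------------------
# statistical behaviour
# --------------------------------------------------------------------------


class TestBias:
    def test_monoexp_median_bias_small_at_snr_30(self):
        """Median relative bias of T-hat under Rician noise at SNR 30."""
        rng = np.random.default_rng(21)
        T, s0, snr = 50.0, 1000.0, 30.0
        sigma = s0 * np.exp(-TE_SE[0] / T) / snr
        clean = s0 * np.exp(-TE_SE / T)
        n = 1000
        y = np.hypot(
            clean[None, :] + rng.normal(0, sigma, (n, TE_SE.size)),
            rng.normal(0, sigma, (n, TE_SE.size)),
        )
        est = np.array(
            [fit_monoexp_noisefloor(TE_SE, yi, sigma).time_ms for yi in y]
        )
        assert abs(np.median(est) / T - 1.0) < 0.02


# --------------------------------------------------------------------------
# map-level fitting
# --------------------------------------------------------------------------


class TestFitMap:
    def test_noiseless_map_equals_ground_truth(self, noiseless_spec, schedules):
        from relaxaniso.phantom import effective_time_ms

        series = generate_series(noiseless_spec, schedules["T2"], 45.0)
        spec = FitModelSpec(model="monoexp_noisefloor", noise_sigma=0.0)
        rmap = fit_map(series, spec)
        truth = effective_time_ms(
            noiseless_spec.depth_of_rows(), 45.0, "T2", noiseless_spec
        )
        got = rmap.times_ms[noiseless_spec.cartilage_rows, :]
        np.testing.assert_allclose(
            got, np.broadcast_to(truth[:, None], got.shape), rtol=1e-4
        )
        assert rmap.converged[rmap.mask].all()

    def test_masked_out_pixels_not_fitted(self, spec, schedules):
        series = generate_series(spec, schedules["T2"], 0.0)
        series.mask = series.mask.copy()
        series.mask[20, 30] = False
        rmap = fit_map(series)
        assert np.isnan(rmap.times_ms[20, 30])
        assert not rmap.converged[20, 30]

    def test_model_kind_mismatch_rejected(self, spec, schedules):
        series = generate_series(spec, schedules["T1"], 0.0)
        with pytest.raises(ValueError):
            fit_map(series, FitModelSpec(model="monoexp_noisefloor"))

    def test_rates_times_reciprocal(self, spec, schedules):
        series = generate_series(spec, schedules["T2"], 60.0)
        rmap = fit_map(series)
        ok = rmap.converged
        np.testing.assert_allclose(
            rmap.rates_s[ok] * rmap.times_ms[ok], 1000.0, rtol=1e-12
        )

    @pytest.mark.parametrize(
        "kind,model",
        [
            ("T1", "inversion_recovery"),
            ("T2", "monoexp_noisefloor"),
            ("CWT1rho_500", "exp_baseline"),
            ("RAFF2", "raff_steadystate"),
            ("AdT2rho", "monoexp_noisefloor"),
        ],
    )
    def test_model_dispatch(self, kind, model):
        assert model_for_kind(kind) == model
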