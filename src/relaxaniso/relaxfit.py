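"""Pixel-wise relaxation-model fitting.

Four signal models cover all parameter kinds:

``monoexp_noisefloor``
    S(t) = S0 exp(-t/T) after quadrature noise-floor subtraction
    s' = sqrt(max(s^2 - sigma^2, 0)); used for T2, T2*, adiabatic trains.
``exp_baseline``
    S(t) = A exp(-t/T) + C; used for CW spin-lock decays.
``inversion_recovery``
    S(t) = S0 |1 - 2 f exp(-t/T1)| on magnitude data, inversion
    efficiency f fitted in [0.5, 1].
``raff_steadystate``
    Joint fit of the non-inverted / inverted pair
    S(t) = SS + (S0 - SS) exp(-t/T) with shared steady state SS and T.

All fitters run a bounded Levenberg-Marquardt iteration vectorised over
pixels, so a whole map is fitted in one call.  Magnitude sign folding
(inversion recovery, inverted RAFF curve) is resolved by trying every
monotone sign-restoration prefix and keeping the lowest-residual fit.
Pixels that fail to converge, or whose time constant lands on a bound,
are flagged rather than silently zeroed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "FitModelSpec",
    "RelaxMap",
    "FitResult",
    "RaffFitResult",
    "estimate_noise_sigma",
    "correct_noise_floor",
    "fit_monoexp_noisefloor",
    "fit_exp_baseline",
    "fit_inversion_recovery",
    "fit_raff_steadystate",
    "fit_map",
    "model_for_kind",
]

_RAYLEIGH_MEAN = np.sqrt(np.pi / 2.0)

# time-constant bounds in ms shared by all models
_T_BOUNDS_MS = (1.0, 10_000.0)


@dataclass(frozen=True)
class FitModelSpec:
    """Configuration of one pixel-wise fit."""

    model: str = "monoexp_noisefloor"
    t_bounds_ms: tuple[float, float] = _T_BOUNDS_MS
    max_iter: int = 200
    tol: float = 1e-12
    noise_sigma: float | None = None

    def __post_init__(self):
        if self.model not in (
            "monoexp_noisefloor",
            "exp_baseline",
            "inversion_recovery",
            "raff_steadystate",
        ):
            raise ValueError(f"unknown model {self.model!r}")
        if self.t_bounds_ms[0] <= 0 or self.t_bounds_ms[1] <= self.t_bounds_ms[0]:
            raise ValueError("invalid time-constant bounds")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


class FitResult(NamedTuple):
    amplitude: float
    time_ms: float
    rss: float
    converged: bool
    baseline: float = 0.0


class RaffFitResult(NamedTuple):
    time_ms: float
    steady_state: float
    amplitude_plain: float
    amplitude_inverted: float
    rss: float
    converged: bool


@dataclass
class RelaxMap:
    """Pixel-wise fitted relaxation map with fit diagnostics.

    ``times_ms`` holds NaN outside the mask; fitted values elsewhere,
    valid only where ``converged`` is True.  ``rates_s`` = 1000/times.
    """

    times_ms: np.ndarray
    amplitude: np.ndarray
    baseline: np.ndarray
    rss: np.ndarray
    converged: np.ndarray
    mask: np.ndarray
    parameter_kind: str
    sample_orientation_deg: float

    @property
    def rates_s(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return 1000.0 / self.times_ms


# --------------------------------------------------------------------------
# noise handling
# --------------------------------------------------------------------------


def estimate_noise_sigma(series) -> float:
    """Gaussian channel sigma from a pure-noise background region.

    Background magnitude pixels are Rayleigh distributed with mean
    sigma * sqrt(pi/2); the estimator inverts that relation using every
    preparation-time frame of the background ROI.
    """
    bg = np.asarray(series.background_roi, dtype=bool)
    n = int(bg.sum())
    if n < 50:
        raise ValueError(f"background ROI too small ({n} pixels, need >= 50)")
    vals = series.data[:, bg]
    return float(vals.mean() / _RAYLEIGH_MEAN)


def correct_noise_floor(signals, sigma: float):
    """Quadrature noise-floor subtraction: sqrt(max(s^2 - sigma^2, 0))."""
    s = np.asarray(signals, dtype=float)
    return np.sqrt(np.clip(s * s - sigma * sigma, 0.0, None))


# --------------------------------------------------------------------------
# vectorised Levenberg-Marquardt core
# --------------------------------------------------------------------------


def _lm(model_jac, y, p0, lo, hi, max_iter, tol):
    """Bounded LM minimisation of ||model(p) - y||^2, vectorised over rows.

    model_jac(p, idx) -> (f, J) with f (n_sub, m), J (n_sub, m, k) for
    the rows ``idx``; p0 (n, k); lo/hi (k,) box bounds (clipped
    projection).  Returns (p, rss, converged) where converged marks rows
    whose last accepted step was below tol in relative parameter change.
    Rows whose damping parameter explodes are abandoned unconverged.
    """
    p = np.clip(np.asarray(p0, dtype=float), lo, hi)
    n, k = p.shape
    idx_all = np.arange(n)
    f, J = model_jac(p, idx_all)
    r = f - y
    rss = np.einsum("nm,nm->n", r, r)
    lam = np.full(n, 1e-3)
    converged = np.zeros(n, dtype=bool)
    done = np.zeros(n, dtype=bool)
    eye = np.eye(k)

    for _ in range(max_iter):
        act = np.flatnonzero(~done)
        if act.size == 0:
            break
        Ja, ra, pa, lama = J[act], r[act], p[act], lam[act]
        JtJ = np.einsum("nmk,nml->nkl", Ja, Ja)
        g = np.einsum("nmk,nm->nk", Ja, ra)
        A = JtJ + lama[:, None, None] * (
            np.einsum("nkk->nk", JtJ)[:, :, None] * eye + 1e-12 * eye
        )
        try:
            step = -np.linalg.solve(A, g[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = -np.linalg.solve(A + 1e-8 * eye, g[..., None])[..., 0]

        # active-set correction: components pushed past a bound are frozen
        # at the bound and the step re-solved for the remaining ones, so a
        # parameter stuck at its bound cannot corrupt the others
        viol = ((pa + step) < lo) | ((pa + step) > hi)
        rows = viol.any(axis=1)
        if rows.any():
            free = ~viol[rows]
            Jf = Ja[rows] * free[:, None, :]
            JtJf = np.einsum("nmk,nml->nkl", Jf, Jf)
            gf = np.einsum("nmk,nm->nk", Jf, ra[rows])
            Af = JtJf + lama[rows, None, None] * (
                np.einsum("nkk->nk", JtJf)[:, :, None] * eye + 1e-12 * eye
            )
            # unit diagonal on frozen components keeps the system regular
            frozen = ~free
            Af = Af + frozen[:, :, None] * eye
            gf = np.where(frozen, 0.0, gf)
            step_f = -np.linalg.solve(Af, gf[..., None])[..., 0]
            target = np.clip(pa[rows] + step[rows], lo, hi)
            step_f = np.where(frozen, target - pa[rows], step_f)
            step[rows] = step_f
        p_new = np.clip(pa + step, lo, hi)
        f_new, J_new = model_jac(p_new, act)
        r_new = f_new - y[act]
        rss_new = np.einsum("nm,nm->n", r_new, r_new)

        better = rss_new <= rss[act]
        scale = np.maximum(np.abs(pa), 1e-30)
        delta = np.max(np.abs(p_new - pa) / scale, axis=1)
        # converged when the (possibly rejected) proposed step is tiny, or
        # an accepted step no longer reduces the residual measurably
        stalled = better & (
            rss[act] - rss_new <= 1e-12 * np.maximum(rss[act], 1e-300)
        )
        conv_now = (delta < tol) | stalled

        upd = act[better]
        p[upd] = p_new[better]
        r[upd] = r_new[better]
        J[upd] = J_new[better]
        rss[upd] = rss_new[better]
        lam[upd] /= 3.0
        lam[act[~better]] *= 10.0
        converged[act[conv_now]] = True
        done[act] = conv_now | (lam[act] > 1e12)
    return p, rss, converged


def _loglin_rate_init(t, y, floor):
    """Rate init (1/ms) from a signal-weighted log-linear regression."""
    yy = np.maximum(np.asarray(y, dtype=float), 1e-300)
    w = np.where(y > floor[:, None], yy * yy, 0.0)
    wsum = w.sum(axis=1)
    ok = wsum > 0
    w = np.where(ok[:, None], w, 1.0)
    wsum = np.where(ok, wsum, w.shape[1])
    ly = np.log(yy)
    tbar = (w * t).sum(axis=1) / wsum
    lbar = (w * ly).sum(axis=1) / wsum
    cov = (w * (t - tbar[:, None]) * (ly - lbar[:, None])).sum(axis=1)
    var = (w * (t - tbar[:, None]) ** 2).sum(axis=1)
    slope = np.where(var > 0, cov / np.maximum(var, 1e-300), 0.0)
    rate = np.clip(-slope, 1e-4, 1.0)
    s0 = np.exp(lbar + rate * tbar)
    return s0, rate


# --------------------------------------------------------------------------
# model fitters (vectorised over a leading pixel axis)
# --------------------------------------------------------------------------


def _fit_monoexp_batch(t, Y, spec: FitModelSpec):
    t = np.asarray(t, dtype=float)
    n = Y.shape[0]
    lo_r, hi_r = 1.0 / spec.t_bounds_ms[1], 1.0 / spec.t_bounds_ms[0]

    def model_jac(p, idx):
        s0, rate = p[:, 0], p[:, 1]
        E = np.exp(-rate[:, None] * t[None, :])
        f = s0[:, None] * E
        J = np.stack([E, -f * t[None, :]], axis=-1)
        return f, J

    floor = np.zeros(n)
    s0_0, r0 = _loglin_rate_init(t, Y, floor)
    p0 = np.stack([np.maximum(s0_0, 1e-12), r0], axis=1)
    lo = np.array([0.0, lo_r])
    hi = np.array([np.inf, hi_r])
    p, rss, conv = _lm(model_jac, Y, p0, lo, hi, spec.max_iter, spec.tol)
    s0, rate = p[:, 0], p[:, 1]
    times = 1.0 / rate
    on_bound = (rate <= lo_r * (1 + 1e-9)) | (rate >= hi_r * (1 - 1e-9))
    all_zero = ~np.any(Y > 0, axis=1)
    conv = conv & ~on_bound & (s0 > 0) & ~all_zero
    return s0, times, rss, conv


def _fit_expbaseline_batch(t, Y, spec: FitModelSpec):
    t = np.asarray(t, dtype=float)
    lo_r, hi_r = 1.0 / spec.t_bounds_ms[1], 1.0 / spec.t_bounds_ms[0]

    def model_jac(p, idx):
        a, c, rate = p[:, 0], p[:, 1], p[:, 2]
        E = np.exp(-rate[:, None] * t[None, :])
        f = a[:, None] * E + c[:, None]
        J = np.stack([E, np.ones_like(E), -a[:, None] * t[None, :] * E], axis=-1)
        return f, J

    c0 = Y[:, -1]
    resid = np.clip(Y - c0[:, None], 1e-12, None)
    s0_0, r0 = _loglin_rate_init(t, resid, np.zeros(Y.shape[0]))
    p0 = np.stack([np.maximum(Y[:, 0] - c0, 1e-9), c0, r0], axis=1)
    lo = np.array([0.0, -np.inf, lo_r])
    hi = np.array([np.inf, np.inf, hi_r])
    p, rss, conv = _lm(model_jac, Y, p0, lo, hi, spec.max_iter, spec.tol)
    a, c, rate = p[:, 0], p[:, 1], p[:, 2]
    times = 1.0 / rate
    on_bound = (rate <= lo_r * (1 + 1e-9)) | (rate >= hi_r * (1 - 1e-9))
    spread = Y.max(axis=1) - Y.min(axis=1)
    degenerate = spread <= 1e-12 * np.maximum(Y.max(axis=1), 1e-300)
    conv = conv & ~on_bound & (a > 0) & ~degenerate
    return a, c, times, rss, conv


def _fit_ir_batch(t, Y, spec: FitModelSpec):
    """Magnitude inversion recovery with sign restoration.

    The polarity fold of the magnitude curve sits at the signal minimum:
    for each pixel the two monotone sign patterns consistent with it
    (first ``argmin`` or ``argmin + 1`` points inverted) are tried and
    the signed model S0 (1 - 2 f exp(-t/T1)) fitted to each restored
    curve; the lowest-residual solution is kept.
    """
    t = np.asarray(t, dtype=float)
    n, m = Y.shape
    lo_r, hi_r = 1.0 / spec.t_bounds_ms[1], 1.0 / spec.t_bounds_ms[0]
    lo = np.array([0.0, 0.5, lo_r])
    hi = np.array([np.inf, 1.0, hi_r])

    def model_jac(p, idx):
        s0, f_eff, rate = p[:, 0], p[:, 1], p[:, 2]
        E = np.exp(-rate[:, None] * t[None, :])
        core = 1.0 - 2.0 * f_eff[:, None] * E
        f = s0[:, None] * core
        J = np.stack(
            [core, -2.0 * s0[:, None] * E,
             2.0 * s0[:, None] * f_eff[:, None] * t[None, :] * E],
            axis=-1,
        )
        return f, J

    jmin = np.argmin(Y, axis=1)
    best = None
    for off in (0, 1):
        kflip = np.clip(jmin + off, 0, m)  # number of inverted leading points
        signs = np.where(np.arange(m)[None, :] < kflip[:, None], -1.0, 1.0)
        Ys = Y * signs

        # null time between the last inverted and first recovered point
        t_pad = np.concatenate([[t[0] * 0.0], t, [t[-1] * 3.0]])
        t_null = 0.5 * (t_pad[kflip] + t_pad[np.minimum(kflip + 1, m + 1)])
        t1_0 = np.clip(
            np.maximum(t_null, t[0] * 0.25) / np.log(2.0),
            spec.t_bounds_ms[0], spec.t_bounds_ms[1],
        )
        p0 = np.stack([np.abs(Y).max(axis=1), np.full(n, 0.95), 1.0 / t1_0], axis=1)
        p, rss, conv = _lm(model_jac, Ys, p0, lo, hi, spec.max_iter, spec.tol)
        if best is None:
            best = [p, rss, conv]
        else:
            take = rss < best[1]
            best[0] = np.where(take[:, None], p, best[0])
            best[2] = np.where(take, conv, best[2])
            best[1] = np.where(take, rss, best[1])
    p, rss, conv = best
    s0, rate = p[:, 0], p[:, 2]
    times = 1.0 / rate
    on_bound = (rate <= lo_r * (1 + 1e-9)) | (rate >= hi_r * (1 - 1e-9))
    conv = conv & ~on_bound & (s0 > 0)
    return s0, times, rss, conv


def _fit_raff_batch(t, Yp, Yi, spec: FitModelSpec):
    """Joint steady-state fit of the (plain, inverted) RAFF pair.

    Shared steady state SS and time constant T; the inverted curve is
    magnitude data whose initial points may be folded, handled by a
    prefix sign search.
    """
    t = np.asarray(t, dtype=float)
    n, m = Yp.shape
    lo_r, hi_r = 1.0 / spec.t_bounds_ms[1], 1.0 / spec.t_bounds_ms[0]
    lo = np.array([-np.inf, -np.inf, -np.inf, lo_r])
    hi = np.array([np.inf, np.inf, np.inf, hi_r])

    def model_jac(p, idx):
        ss, s0p, s0i, rate = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
        E = np.exp(-rate[:, None] * t[None, :])
        fp = ss[:, None] + (s0p - ss)[:, None] * E
        fi = ss[:, None] + (s0i - ss)[:, None] * E
        zeros = np.zeros_like(E)
        dfp = np.stack(
            [1.0 - E, E, zeros, -(s0p - ss)[:, None] * t[None, :] * E], axis=-1
        )
        dfi = np.stack(
            [1.0 - E, zeros, E, -(s0i - ss)[:, None] * t[None, :] * E], axis=-1
        )
        return np.concatenate([fp, fi], axis=1), np.concatenate([dfp, dfi], axis=1)

    # the inverted curve is magnitude data: every monotone sign-restoration
    # prefix (first k points folded) is a legitimate hypothesis; fit them
    # all and keep the lowest joint residual
    best = None
    for k in range(m + 1):
        kflip = np.full(n, k)
        signs = np.where(np.arange(m)[None, :] < kflip[:, None], -1.0, 1.0)
        Yis = Yi * signs
        Yfull = np.concatenate([Yp, Yis], axis=1)
        p0 = np.stack(
            [Yp[:, -1], Yp[:, 0], Yis[:, 0], np.full(n, 2.0 / max(t[-1], 1.0))], axis=1
        )
        p, rss, conv = _lm(model_jac, Yfull, p0, lo, hi, spec.max_iter, spec.tol)
        if best is None:
            best = [p, rss, conv]
        else:
            take = rss < best[1]
            best[0] = np.where(take[:, None], p, best[0])
            best[2] = np.where(take, conv, best[2])
            best[1] = np.where(take, rss, best[1])
    p, rss, conv = best
    ss, s0p, s0i, rate = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    times = 1.0 / rate
    on_bound = (rate <= lo_r * (1 + 1e-9)) | (rate >= hi_r * (1 - 1e-9))
    spread = np.maximum(Yp.max(axis=1) - Yp.min(axis=1), Yi.max(axis=1) - Yi.min(axis=1))
    degenerate = spread <= 1e-12 * np.maximum(np.abs(Yp).max(axis=1), 1e-300)
    conv = conv & ~on_bound & ~degenerate
    return times, ss, s0p, s0i, rss, conv


# --------------------------------------------------------------------------
# scalar API
# --------------------------------------------------------------------------


def _check_curve(prep_times, signals, min_points):
    t = np.asarray(prep_times, dtype=float)
    y = np.asarray(signals, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("prep_times and signals must be 1-D with equal length")
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if np.any(t < 0):
        raise ValueError("negative preparation times are not allowed")
    return t, y


def fit_monoexp_noisefloor(prep_times, signals, sigma=0.0, spec=None):
    """Two-parameter monoexponential fit with noise-floor subtraction."""
    spec = spec or FitModelSpec(model="monoexp_noisefloor")
    t, y = _check_curve(prep_times, signals, 3)
    if np.any(y < 0):
        raise ValueError("magnitude signals must be non-negative")
    yc = correct_noise_floor(y, sigma)
    s0, times, rss, conv = _fit_monoexp_batch(t, yc[None, :], spec)
    return FitResult(float(s0[0]), float(times[0]), float(rss[0]), bool(conv[0]))


def fit_exp_baseline(prep_times, signals, spec=None):
    """Exponential-plus-baseline fit S(t) = A exp(-t/T) + C."""
    spec = spec or FitModelSpec(model="exp_baseline")
    t, y = _check_curve(prep_times, signals, 4)
    a, c, times, rss, conv = _fit_expbaseline_batch(t, y[None, :], spec)
    return FitResult(float(a[0]), float(times[0]), float(rss[0]), bool(conv[0]), float(c[0]))


def fit_inversion_recovery(inversion_times, signals, spec=None):
    """Magnitude inversion-recovery fit S(t) = S0 |1 - 2 f exp(-t/T1)|."""
    spec = spec or FitModelSpec(model="inversion_recovery")
    t, y = _check_curve(inversion_times, signals, 4)
    if np.any(y < 0):
        raise ValueError("magnitude signals must be non-negative")
    s0, times, rss, conv = _fit_ir_batch(t, y[None, :], spec)
    return FitResult(float(s0[0]), float(times[0]), float(rss[0]), bool(conv[0]))


def fit_raff_steadystate(n_pulses, signals_plain, signals_inverted, pulse_duration_ms, spec=None):
    """Joint exponential approach-to-steady-state fit of a RAFF pair."""
    spec = spec or FitModelSpec(model="raff_steadystate")
    npls = np.asarray(n_pulses, dtype=float)
    yp = np.asarray(signals_plain, dtype=float)
    yi = np.asarray(signals_inverted, dtype=float)
    if yp.shape != npls.shape or yi.shape != npls.shape:
        raise ValueError("plain and inverted curves must share the pulse-count axis")
    if pulse_duration_ms <= 0:
        raise ValueError("pulse duration must be positive")
    t = npls * pulse_duration_ms
    times, ss, s0p, s0i, rss, conv = _fit_raff_batch(t, yp[None, :], yi[None, :], spec)
    return RaffFitResult(
        float(times[0]), float(ss[0]), float(s0p[0]), float(s0i[0]),
        float(rss[0]), bool(conv[0]),
    )


# --------------------------------------------------------------------------
# map-level fitting
# --------------------------------------------------------------------------


def model_for_kind(parameter_kind: str) -> str:
    """Fit model used for a given relaxation parameter kind."""
    if parameter_kind == "T1":
        return "inversion_recovery"
    if parameter_kind == "RAFF2":
        return "raff_steadystate"
    if parameter_kind.startswith("CWT1rho"):
        return "exp_baseline"
    return "monoexp_noisefloor"


def fit_map(series, model_spec: FitModelSpec | None = None) -> RelaxMap:
    """Fit every masked pixel of an image series.

    The model defaults to the one appropriate for the series' parameter
    kind; for the noise-floor model, sigma is estimated from the
    background ROI unless given in the model spec.
    """
    kind = series.schedule.parameter_kind
    model = model_for_kind(kind)
    if model_spec is None:
        model_spec = FitModelSpec(model=model)
    elif model_spec.model != model:
        raise ValueError(
            f"model {model_spec.model!r} incompatible with parameter kind {kind!r}"
        )

    mask = np.asarray(series.mask, dtype=bool)
    t = np.asarray(series.schedule.prep_times_ms, dtype=float)
    Y = series.data[:, mask].T  # (npix, nt)
    shape = mask.shape

    def blank():
        return np.full(shape, np.nan)

    times2d, amp2d, base2d, rss2d = blank(), blank(), blank(), blank()
    conv2d = np.zeros(shape, dtype=bool)

    if model == "monoexp_noisefloor":
        sigma = model_spec.noise_sigma
        if sigma is None:
            sigma = estimate_noise_sigma(series)
        Yc = correct_noise_floor(Y, sigma)
        s0, times, rss, conv = _fit_monoexp_batch(t, Yc, model_spec)
        base = np.zeros_like(s0)
    elif model == "exp_baseline":
        s0, base, times, rss, conv = _fit_expbaseline_batch(t, Y, model_spec)
    elif model == "inversion_recovery":
        s0, times, rss, conv = _fit_ir_batch(t, Y, model_spec)
        base = np.zeros_like(s0)
    else:  # raff_steadystate
        Yi = series.data_inverted[:, mask].T
        times, ss, s0, _s0i, rss, conv = _fit_raff_batch(t, Y, Yi, model_spec)
        base = ss

    times2d[mask] = times
    amp2d[mask] = s0
    base2d[mask] = base
    rss2d[mask] = rss
    conv2d[mask] = conv
    return RelaxMap(
        times_ms=times2d,
        amplitude=amp2d,
        baseline=base2d,
        rss=rss2d,
        converged=conv2d,
        mask=mask,
        parameter_kind=kind,
        sample_orientation_deg=series.sample_orientation_deg,
    )
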