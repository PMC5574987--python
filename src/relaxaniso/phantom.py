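"""Synthetic magic-angle cartilage phantom.

Generates multi-orientation relaxometry image series and matched
quantitative polarized light microscopy (qPLM) maps with known ground
truth.  The phantom emulates the tri-laminar collagen architecture of
articular cartilage: a superficial zone (SZ) with fibres parallel to the
articular surface (90 degrees from the surface normal), a transitional
zone (TZ) where the fibre angle arches smoothly towards the surface
normal, and a radial / deep zone (RZ) with fibres along the normal
(0 degrees).

Transverse-type relaxation rates follow the residual dipolar interaction
angular law

    R(depth, phi) = R_iso + c_dip * (3 cos^2 theta_eff - 1)^2 / 4

with ``theta_eff = fibre_angle(depth) - phi`` the angle between the local
fibre axis and the main field B0 when the specimen surface normal is
tilted by ``phi``.  The (3 cos^2 theta - 1)^2 scaling guarantees a
non-negative dipolar excess rate that vanishes at the magic angle
(54.74 degrees); the normalisation by 4 makes ``c_dip`` the full excess
rate at theta = 0.  Longitudinal-type parameters (T1) are
orientation-independent by construction.

Magnitude images carry Rician noise: independent Gaussian noise of
standard deviation sigma on two quadrature channels, with sigma set so
that (mean noiseless foreground signal at the first preparation time) /
sigma equals the requested SNR.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PARAMETER_KINDS",
    "TRANSVERSE_KINDS",
    "LONGITUDINAL_KINDS",
    "RelaxParams",
    "DEFAULT_RELAX_PARAMS",
    "PhantomSpec",
    "AcquisitionSchedule",
    "ImageSeries",
    "PLMMaps",
    "default_schedules",
    "fibre_angle_profile",
    "dipolar_factor",
    "magic_angle_deg",
    "true_rate",
    "true_time_ms",
    "effective_rate",
    "effective_time_ms",
    "generate_series",
    "generate_plm_maps",
]


# --------------------------------------------------------------------------
# parameter kinds
# --------------------------------------------------------------------------

#: All relaxation parameter variants handled by the pipeline.  CW spin-lock
#: variants are keyed by their spin-lock amplitude in Hz, adiabatic T1rho
#: variants by the hyperbolic-secant pulse shape of the train.
PARAMETER_KINDS = (
    "T1",
    "T2",
    "T2star",
    "AdT1rho_HS1",
    "AdT1rho_HS4",
    "AdT1rho_HS8",
    "AdT2rho",
    "RAFF2",
    "CWT1rho_250",
    "CWT1rho_500",
    "CWT1rho_1000",
    "CWT1rho_2000",
)

LONGITUDINAL_KINDS = ("T1",)
TRANSVERSE_KINDS = tuple(k for k in PARAMETER_KINDS if k not in LONGITUDINAL_KINDS)


@dataclass(frozen=True)
class RelaxParams:
    """Ground-truth relaxation parameters for one parameter kind.

    r_iso
        Orientation-independent (isotropic) relaxation rate, 1/s.
    c_dip
        Dipolar excess rate at theta = 0, 1/s.  Zero for
        orientation-independent kinds.
    t1_ms
        Longitudinal relaxation time for T1-type kinds, ms (ignored for
        transverse kinds).
    """

    r_iso: float
    c_dip: float
    t1_ms: float | None = None


# Defaults chosen so that (a) relaxation times at the magic angle sit in the
# physiological range of deep bovine cartilage at high field and (b) the
# noiseless deep-zone Michelson anisotropy over a 0-90 degree orientation
# sweep reproduces the observed ordering of orientation sensitivity:
# T2 ~ T2* > adiabatic T2rho > RAFF2 > CW-T1rho (250) > (500) > (1000)
# > adiabatic T1rho HS4 ~ HS8 > CW-T1rho (2000) > adiabatic T1rho HS1 >> T1.
DEFAULT_RELAX_PARAMS: dict[str, RelaxParams] = {
    "T1": RelaxParams(r_iso=1000.0 / 1400.0, c_dip=0.0, t1_ms=1400.0),
    "T2": RelaxParams(r_iso=14.5, c_dip=157.4),
    "T2star": RelaxParams(r_iso=17.0, c_dip=176.0),
    "AdT2rho": RelaxParams(r_iso=12.5, c_dip=75.9),
    "RAFF2": RelaxParams(r_iso=10.4, c_dip=57.5),
    "CWT1rho_250": RelaxParams(r_iso=11.8, c_dip=50.5),
    "CWT1rho_500": RelaxParams(r_iso=11.1, c_dip=18.9),
    "CWT1rho_1000": RelaxParams(r_iso=10.3, c_dip=6.4),
    "AdT1rho_HS4": RelaxParams(r_iso=6.9, c_dip=3.1),
    "AdT1rho_HS8": RelaxParams(r_iso=6.7, c_dip=3.0),
    "CWT1rho_2000": RelaxParams(r_iso=9.3, c_dip=2.7),
    "AdT1rho_HS1": RelaxParams(r_iso=4.5, c_dip=0.7),
}


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth description of the synthetic specimen.

    The cartilage slab occupies ``cartilage_depth_px`` rows starting at
    ``surface_row``; depth fraction runs from 0 at the articular surface
    to 1 at the cartilage-bone interface.  ``sz_end`` / ``rz_start`` are
    the depth fractions bounding the transitional arcade of the fibre
    angle profile.  ``dispersion_deg`` gives the standard deviation of
    the local fibre angle per zone (SZ, TZ, RZ); it is maximal in the TZ
    where fibre organisation is weakest.
    """

    image_shape: tuple[int, int] = (64, 64)
    pixel_size_mm: float = 0.0625
    surface_row: int = 8
    cartilage_depth_px: int = 48
    sz_end: float = 0.10
    rz_start: float = 0.30
    sz_orientation_deg: float = 90.0
    dispersion_deg: tuple[float, float, float] = (10.0, 25.0, 5.0)
    relax_params: dict[str, RelaxParams] = field(
        default_factory=lambda: dict(DEFAULT_RELAX_PARAMS)
    )
    snr: float = 40.0
    s0: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.sz_end < self.rz_start <= 1.0):
            raise ValueError("require 0 < sz_end < rz_start <= 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for kind, p in self.relax_params.items():
            if p.c_dip < 0 or p.r_iso <= 0:
                raise ValueError(f"invalid relaxation parameters for {kind!r}")
        last = self.surface_row + self.cartilage_depth_px
        if last > self.image_shape[0]:
            raise ValueError("cartilage extends beyond the image")

    def with_seed(self, seed: int) -> "PhantomSpec":
        return replace(self, seed=int(seed))

    # geometry helpers -----------------------------------------------------
    @property
    def cartilage_rows(self) -> slice:
        return slice(self.surface_row, self.surface_row + self.cartilage_depth_px)

    def tissue_mask(self) -> np.ndarray:
        m = np.zeros(self.image_shape, dtype=bool)
        m[self.cartilage_rows, :] = True
        return m

    def background_mask(self) -> np.ndarray:
        """Noise-only region: rows at least 2 pixels away from the tissue."""
        m = np.zeros(self.image_shape, dtype=bool)
        top = self.surface_row - 2
        if top > 0:
            m[:top, :] = True
        bottom = self.surface_row + self.cartilage_depth_px + 2
        if bottom < self.image_shape[0]:
            m[bottom:, :] = True
        return m

    def depth_of_rows(self) -> np.ndarray:
        """Depth fraction of each cartilage row centre (surface row = 0)."""
        n = self.cartilage_depth_px
        return np.arange(n) / (n - 1)


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Preparation-time axis of one relaxometry acquisition.

    ``prep_times_ms`` are inversion times (T1), echo times (T2/T2*),
    spin-lock durations (CW-T1rho) or pulse-train durations
    (n_pulses x pulse_duration_ms for the adiabatic and RAFF trains).
    """

    parameter_kind: str
    prep_times_ms: tuple[float, ...]
    spinlock_amplitude_hz: float | None = None
    pulse_duration_ms: float | None = None
    n_pulses: tuple[int, ...] | None = None
    has_inversion_pair: bool = False

    def __post_init__(self):
        if self.parameter_kind not in PARAMETER_KINDS:
            raise ValueError(f"unknown parameter kind {self.parameter_kind!r}")
        t = np.asarray(self.prep_times_ms, dtype=float)
        if t.size < 4:
            raise ValueError("need at least 4 preparation times")
        if not np.all(np.diff(t) > 0):
            raise ValueError("prep_times_ms must be strictly increasing")

    def __len__(self) -> int:
        return len(self.prep_times_ms)


def default_schedules() -> dict[str, AcquisitionSchedule]:
    """Acquisition schedules for all parameter kinds.

    Inversion recovery TI = 0.2-3 s; spin-echo TE up to 128 ms; multi-echo
    gradient-echo TE up to 37.5 ms; CW spin-lock durations up to 192 ms;
    adiabatic pulse trains of 0-24 pulses of 4.5 ms; RAFF trains of 0-8
    pulses of 9 ms acquired with and without inversion preparation.
    """
    sched: dict[str, AcquisitionSchedule] = {}
    sched["T1"] = AcquisitionSchedule("T1", (200.0, 500.0, 800.0, 1100.0, 1400.0, 3000.0))
    sched["T2"] = AcquisitionSchedule("T2", (10.0, 20.0, 40.0, 80.0, 100.0, 128.0))
    sched["T2star"] = AcquisitionSchedule(
        "T2star", (2.5, 7.5, 12.5, 17.5, 22.5, 27.5, 32.5, 37.5)
    )
    for amp in (250, 500, 1000, 2000):
        sched[f"CWT1rho_{amp}"] = AcquisitionSchedule(
            f"CWT1rho_{amp}", (0.0, 24.0, 48.0, 96.0, 192.0), spinlock_amplitude_hz=amp
        )
    ad_pulses = (0, 4, 8, 12, 24)
    for shape in ("HS1", "HS4", "HS8"):
        sched[f"AdT1rho_{shape}"] = AcquisitionSchedule(
            f"AdT1rho_{shape}",
            tuple(4.5 * n for n in ad_pulses),
            pulse_duration_ms=4.5,
            n_pulses=ad_pulses,
        )
    sched["AdT2rho"] = AcquisitionSchedule(
        "AdT2rho", tuple(4.5 * n for n in ad_pulses), pulse_duration_ms=4.5, n_pulses=ad_pulses
    )
    raff_pulses = (0, 2, 4, 6, 8)
    sched["RAFF2"] = AcquisitionSchedule(
        "RAFF2",
        tuple(9.0 * n for n in raff_pulses),
        pulse_duration_ms=9.0,
        n_pulses=raff_pulses,
        has_inversion_pair=True,
    )
    return sched


# --------------------------------------------------------------------------
# image containers
# --------------------------------------------------------------------------


@dataclass
class ImageSeries:
    """One relaxometry acquisition: a magnitude image per preparation time.

    ``data`` is (n_prep, rows, cols), non-negative.  For acquisitions with
    an inversion-prepared twin (RAFF), ``data_inverted`` holds the second
    stack on the same preparation axis.
    """

    data: np.ndarray
    schedule: AcquisitionSchedule
    sample_orientation_deg: float
    mask: np.ndarray
    background_roi: np.ndarray
    data_inverted: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_prep, rows, cols)")
        if self.data.shape[0] != len(self.schedule):
            raise ValueError("stack length must equal schedule length")
        if np.any(self.data < 0):
            raise ValueError("magnitude data must be non-negative")
        if np.any(self.mask & self.background_roi):
            raise ValueError("mask and background_roi must be disjoint")
        if self.schedule.has_inversion_pair and self.data_inverted is None:
            raise ValueError("schedule declares an inversion pair but none given")


@dataclass
class PLMMaps:
    """qPLM output maps: collagen orientation (degrees, [0, 180)) and
    optical retardation (arbitrary units, >= 0) per pixel."""

    orientation: np.ndarray
    retardation: np.ndarray
    mask: np.ndarray
    pixel_size_um: float = 2.53

    def __post_init__(self):
        self.orientation = np.asarray(self.orientation, dtype=float)
        self.retardation = np.asarray(self.retardation, dtype=float)
        if np.any((self.orientation < 0) | (self.orientation >= 180.0)):
            raise ValueError("orientation must be wrapped to [0, 180)")
        if np.any(self.retardation < 0):
            raise ValueError("retardation must be non-negative")


# --------------------------------------------------------------------------
# forward model
# --------------------------------------------------------------------------


def fibre_angle_profile(depth_fraction, spec: PhantomSpec | None = None):
    """Collagen fibre angle (degrees from the surface normal) vs depth.

    Constant ``sz_orientation_deg`` (default 90) through the superficial
    zone, 0 through the radial zone, joined by a smooth monotone raised-
    cosine arcade through the transitional zone.
    """
    spec = spec or PhantomSpec()
    d = np.asarray(depth_fraction, dtype=float)
    if np.any((d < 0) | (d > 1)):
        raise ValueError("depth_fraction must lie in [0, 1]")
    u = np.clip((d - spec.sz_end) / (spec.rz_start - spec.sz_end), 0.0, 1.0)
    angle = spec.sz_orientation_deg * 0.5 * (1.0 + np.cos(np.pi * u))
    return angle if angle.ndim else float(angle)


def dipolar_factor(theta_deg):
    """Residual dipolar angular factor 3 cos^2(theta) - 1.

    Vanishes at the magic angle 54.74 degrees; 180-degree periodic and
    symmetric about 0.
    """
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    out = 3.0 * np.cos(th) ** 2 - 1.0
    return out if out.ndim else float(out)


def magic_angle_deg(xtol: float = 1e-12) -> float:
    """Numerical root of the dipolar factor on [0, 90] degrees."""
    from scipy.optimize import brentq

    return float(brentq(dipolar_factor, 0.0, 90.0, xtol=xtol))


def true_rate(depth_fraction, sample_orientation_deg, parameter_kind, spec=None):
    """Ground-truth relaxation rate (1/s) at a depth and sample orientation.

    Transverse-type kinds follow the squared dipolar law; T1-type kinds
    are constant in orientation.
    """
    spec = spec or PhantomSpec()
    if parameter_kind not in PARAMETER_KINDS:
        raise ValueError(f"unknown parameter kind {parameter_kind!r}")
    p = spec.relax_params[parameter_kind]
    if parameter_kind in LONGITUDINAL_KINDS:
        rate = np.full_like(np.asarray(depth_fraction, dtype=float), 1000.0 / p.t1_ms)
        return rate if rate.ndim else float(rate)
    theta_eff = fibre_angle_profile(depth_fraction, spec) - np.asarray(
        sample_orientation_deg, dtype=float
    )
    rate = p.r_iso + p.c_dip * dipolar_factor(theta_eff) ** 2 / 4.0
    return rate if np.ndim(rate) else float(rate)


def true_time_ms(depth_fraction, sample_orientation_deg, parameter_kind, spec=None):
    """Ground-truth relaxation time in ms (1000 / rate)."""
    return 1000.0 / true_rate(depth_fraction, sample_orientation_deg, parameter_kind, spec)


# 21-node Gauss-Hermite rule for averaging over the fibre-angle distribution
_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(21)


def _dispersion_of_depth(depth, spec: "PhantomSpec"):
    d = np.asarray(depth, dtype=float)
    sz, tz, rz = spec.dispersion_deg
    return np.where(d < spec.sz_end, sz, np.where(d < spec.rz_start, tz, rz))


def effective_rate(depth_fraction, sample_orientation_deg, parameter_kind, spec=None):
    """Voxel-average relaxation rate (1/s) including fibre-angle dispersion.

    Within a voxel the fibre axis is dispersed around the mean depth
    profile with the zone's angular standard deviation; the observable
    decay rate is the expectation of the dipolar law over that Gaussian
    distribution (Gauss-Hermite quadrature).  Dispersion is maximal in
    the transitional zone, which flattens the orientation dependence
    there — the mechanism behind the anisotropy minimum at the TZ.
    Reduces to ``true_rate`` where the dispersion is zero.
    """
    spec = spec or PhantomSpec()
    if parameter_kind not in PARAMETER_KINDS:
        raise ValueError(f"unknown parameter kind {parameter_kind!r}")
    p = spec.relax_params[parameter_kind]
    d = np.atleast_1d(np.asarray(depth_fraction, dtype=float))
    if parameter_kind in LONGITUDINAL_KINDS:
        rate = np.full(d.shape, 1000.0 / p.t1_ms)
        return rate if np.ndim(depth_fraction) else float(rate[0])
    mu = np.deg2rad(
        fibre_angle_profile(d, spec) - float(sample_orientation_deg)
    )
    sigma = np.deg2rad(_dispersion_of_depth(d, spec))
    theta = mu[:, None] + np.sqrt(2.0) * sigma[:, None] * _GH_NODES[None, :]
    fac = (3.0 * np.cos(theta) ** 2 - 1.0) ** 2 / 4.0
    efac = (fac * _GH_WEIGHTS[None, :]).sum(axis=1) / np.sqrt(np.pi)
    rate = p.r_iso + p.c_dip * efac
    return rate if np.ndim(depth_fraction) else float(rate[0])


def effective_time_ms(depth_fraction, sample_orientation_deg, parameter_kind, spec=None):
    """Voxel-average relaxation time in ms (1000 / effective_rate)."""
    return 1000.0 / effective_rate(
        depth_fraction, sample_orientation_deg, parameter_kind, spec
    )


# --------------------------------------------------------------------------
# signal models
# --------------------------------------------------------------------------


def _noiseless_stacks(spec: PhantomSpec, schedule: AcquisitionSchedule, phi: float):
    """Noiseless signal stack(s) for one acquisition.

    Returns (plain stack, inverted stack or None), shape (nt, rows, cols).
    """
    nrow, ncol = spec.image_shape
    t = np.asarray(schedule.prep_times_ms, dtype=float)
    nt = t.size
    kind = schedule.parameter_kind

    stack = np.zeros((nt, nrow, ncol))
    stack_inv = None
    depth = spec.depth_of_rows()

    if kind == "T1":
        t1 = spec.relax_params["T1"].t1_ms
        curve = spec.s0 * np.abs(1.0 - 2.0 * np.exp(-t / t1))  # same at all depths
        stack[:, spec.cartilage_rows, :] = curve[:, None, None]
        return stack, None

    rate_ms = effective_rate(depth, phi, kind, spec) / 1000.0  # 1/ms per row
    decay = np.exp(-t[:, None] * rate_ms[None, :])  # (nt, ndepth)

    if kind == "RAFF2":
        ss = 0.25 * spec.s0
        plain = ss + (spec.s0 - ss) * decay
        inv = np.abs(ss + (-spec.s0 - ss) * decay)
        stack[:, spec.cartilage_rows, :] = plain[:, :, None]
        stack_inv = np.zeros_like(stack)
        stack_inv[:, spec.cartilage_rows, :] = inv[:, :, None]
        return stack, stack_inv

    if kind.startswith("CWT1rho"):
        # small orientation-independent baseline from long-T components
        baseline = 0.05 * spec.s0
        curve = (spec.s0 - baseline) * decay + baseline
    else:
        curve = spec.s0 * decay
    stack[:, spec.cartilage_rows, :] = curve[:, :, None]
    return stack, None


def _series_rng(spec: PhantomSpec, label: str, phi: float) -> np.random.Generator:
    """Deterministic per-series generator derived from the spec seed."""
    key = zlib.crc32(f"{label}:{phi:.4f}".encode())
    return np.random.default_rng(np.random.SeedSequence([spec.seed, key]))


def _rician(rng: np.random.Generator, signal: np.ndarray, sigma: float) -> np.ndarray:
    re = signal + rng.normal(0.0, sigma, signal.shape)
    im = rng.normal(0.0, sigma, signal.shape)
    return np.hypot(re, im)


def generate_series(
    spec: PhantomSpec,
    schedule: AcquisitionSchedule,
    sample_orientation_deg: float,
) -> ImageSeries:
    """Generate one noisy magnitude image series for one orientation.

    Noise sigma is (mean noiseless foreground signal at the first prep
    time) / spec.snr; ``spec.snr = inf`` disables noise.  Output is
    bit-reproducible for a fixed spec.
    """
    phi = float(sample_orientation_deg)
    mask = spec.tissue_mask()
    bg = spec.background_mask()
    plain, inv = _noiseless_stacks(spec, schedule, phi)

    if np.isfinite(spec.snr):
        sigma = float(plain[0][mask].mean()) / spec.snr
        rng = _series_rng(spec, schedule.parameter_kind, phi)
        plain = _rician(rng, plain, sigma)
        if inv is not None:
            inv = _rician(rng, inv, sigma)
    return ImageSeries(
        data=plain,
        schedule=schedule,
        sample_orientation_deg=phi,
        mask=mask,
        background_roi=bg,
        data_inverted=inv,
    )


# --------------------------------------------------------------------------
# qPLM maps
# --------------------------------------------------------------------------


# control points of the retardation depth profile: moderate at the surface,
# minimum in the transitional zone, rising monotonically into the deep tissue
_RETARDATION_KNOTS = ((0.0, 0.50), (0.14, 0.30), (0.30, 0.60), (1.0, 1.00))


def generate_plm_maps(spec: PhantomSpec, within_window_frac: float = 0.25,
                      correlation_px: float = 6.0) -> PLMMaps:
    """Matched qPLM orientation and retardation maps for the phantom.

    Orientation is the fibre-angle depth profile plus zero-mean angular
    dispersion (largest in the TZ), wrapped to [0, 180).  Collagen
    orientation varies smoothly at the micrometre scale, so the
    dispersion is split into a spatially correlated field (Gaussian
    random field, correlation length ``correlation_px`` pixels) and an
    independent per-pixel part carrying ``within_window_frac`` of the
    zone's standard deviation; the per-pixel total std stays at the
    configured dispersion while local neighbourhoods see only its
    within-window share, as in real sections.  Retardation is lowest in
    the TZ and increases towards the deep tissue, with small
    multiplicative noise.
    """
    from scipy.ndimage import gaussian_filter

    nrow, ncol = spec.image_shape
    depth = spec.depth_of_rows()
    mask = spec.tissue_mask()
    rng = _series_rng(spec, "qPLM", 0.0)

    base = fibre_angle_profile(depth, spec)
    disp = _dispersion_of_depth(depth, spec)
    shape = (len(depth), ncol)
    white = rng.normal(0.0, 1.0, shape)
    if correlation_px > 0:
        smooth = gaussian_filter(white, correlation_px, mode="reflect")
        std = smooth.std()
        smooth = smooth / std if std > 0 else smooth
    else:
        smooth = white
    frac = float(np.clip(within_window_frac, 0.0, 1.0))
    field = (
        np.sqrt(1.0 - frac**2) * smooth + frac * rng.normal(0.0, 1.0, shape)
    )
    ori = np.zeros((nrow, ncol))
    ori_cart = base[:, None] + field * disp[:, None]
    ori[spec.cartilage_rows, :] = np.mod(ori_cart, 180.0)

    xs = np.array([k[0] for k in _RETARDATION_KNOTS])
    ys = np.array([k[1] for k in _RETARDATION_KNOTS])
    ret_profile = np.interp(depth, xs, ys)
    ret = np.zeros((nrow, ncol))
    noise = np.exp(rng.normal(0.0, 0.03, (len(depth), ncol)))
    ret[spec.cartilage_rows, :] = ret_profile[:, None] * noise
    return PLMMaps(orientation=ori, retardation=ret, mask=mask)
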