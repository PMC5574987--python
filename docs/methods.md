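# Methods

## Forward model of the phantom

The phantom is a flat cartilage slab of 48 rows × 64 columns at
62.5 µm depth resolution (image 64×64, surface at row 8), with the
normalized depth coordinate d ∈ [0, 1] running from the articular
surface to the cartilage–bone interface.

**Fibre architecture.** The mean collagen fibre angle relative to the
surface normal is 90° through the superficial zone (d < 0.10), 0°
through the radial zone (d ≥ 0.30), joined by a smooth monotone
raised-cosine arcade across the transitional zone. Around this mean the
local fibre angle is dispersed with a zone-dependent standard deviation
(defaults 10° / 25° / 5° for SZ / TZ / RZ): fibre organisation is
weakest in the TZ.

**Relaxation rates.** Transverse-type parameters follow the residual
dipolar law. With θ_eff = fibre_angle(d) − φ for a specimen tilted by φ,
the point law is

    R(d, φ) = R_iso + c_dip · (3 cos²θ_eff − 1)² / 4,

so `c_dip` is the full excess rate at θ_eff = 0 and the dipolar term
vanishes at the magic angle (54.74°). The squared form is the standard
second-order scaling of residual-dipolar line broadening; it guarantees
a non-negative excess rate. The *observable* voxel rate additionally
averages this law over the local Gaussian fibre-angle distribution
(21-node Gauss–Hermite quadrature; `effective_rate`). This intravoxel
averaging is what produces the anisotropy minimum in the transitional
zone: where dispersion is large, the orientation dependence of the
voxel-average rate flattens, whatever the mean angle does. With zero
dispersion the voxel rate reduces exactly to the point law. T1 is
orientation-independent by construction (R = 1/T1_true, default
T1 = 1400 ms).

Per-kind defaults (`DEFAULT_RELAX_PARAMS`) place the magic-angle
relaxation times in the physiological range of deep bovine cartilage at
high field and were derived analytically — by inverting the deep-zone
Michelson contrast of the noiseless forward model on the 7-point
orientation grid — so that the configured orientation-sensitivity
ordering spans the observed spectrum from T2 (deep-zone contrast
≈ 80%) down to adiabatic T1ρ with HS1 pulses (≈ 7%) and T1 (0). The
HS4 / HS8 variants are configured 0.3 percentage points apart, i.e.
deliberately inside each other's replicate-to-replicate ranges; no
statistic at four replicates can order that pair, and tests treat it
as tied.

**Signal models.** Spin echo / gradient echo / pulse-train parameters
decay as S(t) = S0·exp(−t·R); CW spin-lock decays carry a small
orientation-independent baseline (5% of S0, long-T1ρ components);
inversion recovery follows S(TI) = S0·|1 − 2·exp(−TI/T1)|; RAFF is the
pair S(t) = SS + (S0 − SS)·exp(−t/T) with non-inverted (S0 = +S0) and
inverted (S0 = −S0) preparations and steady state SS = 0.25·S0. The
preparation-time axes are the acquisition schedules of the study design
(TI 0.2–3 s; TE 10–128 ms spin echo and 2.5–37.5 ms multi-echo GRE;
spin-lock 0–192 ms at 250/500/1000/2000 Hz; adiabatic trains of 0–24
pulses × 4.5 ms; RAFF trains of 0–8 pulses × 9 ms).

**Noise.** Magnitude Rician: independent zero-mean Gaussian noise of
standard deviation σ on two quadrature channels,
σ = (mean noiseless foreground signal at the first preparation time) /
SNR; default SNR 40, within the 30–70 range typical of such
acquisitions. `snr = inf` disables noise. All randomness derives from
one integer seed (per-series substreams keyed by parameter kind and
orientation), so identical specs yield bit-identical images.

**qPLM maps.** The orientation map is the fibre-angle profile plus
dispersion, wrapped to [0, 180). Because real sections vary smoothly at
the 2.5 µm pixel scale, the dispersion splits into a spatially
correlated Gaussian random field (correlation length 6 px) carrying
~97% of the variance and an independent per-pixel share (25% of the
zone σ): the per-pixel standard deviation stays at the configured
dispersion while a 5×5 window sees mostly its local share — without
this, a window of iid draws occupies ~25 distinct histogram bins in
every zone and the entropy filter saturates. Retardation follows the
shape reported for cartilage sections — moderate at the surface, lowest
in the TZ, rising monotonically into the deep tissue — with 3%
multiplicative log-normal noise. One consequence: retardation and MR
anisotropy share their depth trend here, so their correlation is
positive, and its sign should not be compared against measurements
where per-sample retardation behaves differently.

## Fitting

All models are fitted by a bounded Levenberg–Marquardt iteration
vectorised over pixels (per-pixel damping, active-set handling of box
bounds so a parameter pinned at a bound cannot corrupt the step of the
others). Time constants are bounded to [1 ms, 10 s]; convergence is a
relative parameter step below 1e−12 or residual stagnation; pixels
ending on a bound or failing to converge are flagged, never zeroed.
The optimum was cross-checked against `scipy.optimize.curve_fit`
(agreement to ~9 significant digits on Monte-Carlo curves) and against
a dense log-grid search oracle in the test suite; the vectorised
implementation exists because the study fits ~10⁶ curves
(4 specimens × 12 kinds × 7 orientations × ~3k pixels); per-curve
optimiser calls would dominate the runtime.

Noise-floor handling for the monoexponential kinds is quadrature
subtraction s' = √max(s² − σ², 0) before fitting, with σ estimated
from the background ROI via the Rayleigh mean (σ̂ = mean/√(π/2)).
Magnitude polarity for inversion recovery and the inverted RAFF curve
is restored by sign-prefix hypotheses: IR tries the two monotone
prefixes consistent with the signal minimum; RAFF tries every prefix
(the pair fit is cheap) and keeps the lowest joint residual. Inversion
efficiency f is fitted in [0.5, 1].

Known estimator limits at the study conditions: with the 5-point
spin-lock schedule and three free parameters, the CW-T1ρ map-median
error at SNR 40 is 6–10% (scipy reproduces the same numbers — this is
estimator variance, not an optimisation defect), and adiabatic T1ρ-HS1
(T ≈ 205 ms sampled only to 108 ms) sits near 6%. The well-conditioned
kinds fit to 1.5–4.5% median error; median *bias* is below 2% for all
four models at SNR 30.

## Profiling and statistics

Profiles are per-row means over a round(1.75 mm / 0.0625 mm) = 28-column
band centred on the specimen midline, between the per-column median
surface and bone interfaces (first/last foreground pixel; columns with
fewer than 5 foreground pixels excluded). Rows where fewer than half
the band's pixels converged are marked missing and linearly bridged.
Raw profiles are resampled by linear interpolation onto a uniform
100-point depth axis. Zone statistics use SZ [0, 0.08), TZ [0.08, 0.20),
RZ [0.20, 1] by default (the phantom's own fibre arcade spans 0.10–0.30;
zone bounds are configuration, not geometry) and zone means are
integral (trapezoidal) means over the zone interval, which keeps the
statistic stable under profile refinement.

The Michelson contrast is computed on rates (1/T) per depth point over
all orientations with at least two finite values; with exactly two
orientations it is identical whether computed from rates or times.
Values stay in [0, 1] internally; reports multiply by 100. The deep-zone
bulk value averages d ∈ [0.40, 0.80], safely inside the region of
constant fibre angle. An optional 3-MAD trimmed variant guards against
outlier orientations but is off by default (the plain statistic is the
reference behaviour). Noise biases the per-depth max/min spread upward,
which is why the measured T1 deep-zone value is small but nonzero
(~0.7% at SNR 40) rather than exactly 0.

The entropy filter quantizes angles to 256 uniform bins over [0, 180°)
and computes base-2 Shannon entropy of the 5×5 neighbourhood histogram
with symmetric border padding, matching the classic `entropyfilt`
behaviour exactly (verified against a brute-force per-pixel oracle).
That reference behaviour inflates entropy where orientations straddle
the 0°/180° seam; the optional circular mode re-centres each window on
its circular mean (placed at a bin centre) before binning, which
removes the seam — angle-doubling alone would only move the seam, so it
is not used. Orientation profiles average circularly with a 180° period.

Pearson correlations between MR-anisotropy and qPLM profiles use the
full common depth axis with pairwise missing-value removal (no edge
trimming); per-sample coefficients are averaged as tanh(mean(atanh r)).
|r| = 1 (possible only in degenerate synthetic comparisons) is clipped
to the representable z-range and flagged.

## What the phantom does and does not show

Passing the phantom study shows that the chain — generation → fitting →
profiling → contrast statistic → correlation — recovers the angular
structure it encodes: the magic-angle maximum at the grid point nearest
54.74°, the TZ anisotropy minimum and RZ maximum, the configured
orientation-sensitivity ranking, near-unity correlation of
orientation-sensitive kinds with collagen anisotropy and near-zero for
T1. The phantom does not emulate B0/B1 inhomogeneity, susceptibility
effects, curved surfaces, partial-volume mixing at interfaces, bone or
noise texture, spin dynamics of the adiabatic/spin-lock preparations,
or the full 3-D fibre geometry (azimuthal spread enters only as planar
dispersion); agreement on real data depends on those factors as well.

## Problem sizes

Default study: 4 specimens × 12 parameter kinds × 7 orientations on a
64×64 image (3072 tissue pixels), ~15 s end to end on one CPU.
Monte-Carlo assessments in the tests use 1000 curves per model; the
acceptance script re-runs the full default study plus a T2 orientation
sweep and error audit in well under a minute.
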