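# relaxaniso

Orientation-anisotropy analysis of multi-orientation quantitative MRI
relaxometry in layered collagenous tissue, benchmarked against
quantitative polarized light microscopy (qPLM).

## The problem

In highly ordered tissues such as articular cartilage, transverse-type
MRI relaxation parameters (T2, T2\*, rotating-frame variants) depend on
the angle θ between the collagen fibre axis and the main field B0
through the residual dipolar interaction, which scales with
(3 cos²θ − 1) and vanishes at the **magic angle** 54.74°. Longitudinal
relaxation (T1) is essentially orientation-independent. Quantifying how
orientation-sensitive each parameter is matters for choosing robust
quantitative imaging biomarkers: a parameter that changes with patient
positioning is hard to use diagnostically.

`relaxaniso` implements the full analysis chain for a specimen imaged at
several orientations relative to B0:

1. **Phantom** (`relaxaniso.phantom`) — a synthetic magic-angle cartilage
   specimen with the tri-laminar fibre architecture (superficial /
   transitional / radial zones), the dipolar angular law
   `R = R_iso + c_dip·(3cos²θ_eff − 1)²/4` averaged over the local
   fibre-angle dispersion, Rician magnitude noise at configurable SNR,
   and matched qPLM orientation/retardation maps. Fully seeded and
   bit-reproducible.
2. **Pixel-wise fitting** (`relaxaniso.relaxfit`) — vectorised bounded
   Levenberg–Marquardt fits of four signal models: monoexponential with
   quadrature noise-floor subtraction (T2, T2\*, adiabatic trains),
   exponential-plus-baseline (CW spin-lock), magnitude inversion
   recovery `S0·|1 − 2f·e^(−TI/T1)|`, and the joint
   exponential-approach-to-steady-state fit of the inverted /
   non-inverted RAFF pair.
3. **Depth profiling** (`relaxaniso.profiling`) — per-row means over a
   1.75 mm centre band from the articular surface (depth 0) to the bone
   interface (depth 1), depth-normalized, with SZ/TZ/RZ zone statistics.
4. **MR anisotropy** (`relaxaniso.anisotropy`) — the Michelson contrast
   of relaxation rates over sample orientations, per depth point:

       A = (R_max − R_min) / (R_max + R_min),  A ∈ [0, 1]

   reported ×100, with the deep-zone bulk value averaged over 40–80%
   depth.
5. **qPLM anisotropy** (`relaxaniso.plm`) — 5×5 Shannon-entropy filter
   on the collagen-orientation map (256 bins over [0, 180°)), anisotropy
   `1/(entropy + 1)`, plus circular orientation and retardation
   profiles.
6. **Correlation** (`relaxaniso.correlate`) — per-sample Pearson r of
   the MR anisotropy profile against the qPLM anisotropy and retardation
   profiles, averaged across samples via Fisher's z transform
   `r̄ = tanh(mean(atanh(r_i)))`.
7. **Pipeline** (`relaxaniso.pipeline`, `relaxaniso` CLI) — end-to-end
   orchestration with config validation, seeded determinism, and a
   report bundle (summary, zone statistics, tidy profiles, manifest).

## Worked example

```python
from relaxaniso import run_all

result = run_all({"seed": 1, "n_samples": 2,
                  "parameter_kinds": ["T2", "RAFF2", "CWT1rho_500", "T1"]})
print(result["summary"][["parameter_kind", "anisotropy_mean_pct",
                         "r_plm_anisotropy"]].round(2).to_string(index=False))
```

prints

```
parameter_kind  anisotropy_mean_pct  r_plm_anisotropy
            T2                79.79              0.91
         RAFF2                69.58              0.91
   CWT1rho_500                44.33              0.91
            T1                 0.72             -0.04
```

Deep-zone anisotropy (percent) ranks the parameters by orientation
sensitivity: T2 is strongly modulated by specimen orientation (≈80%
Michelson contrast in the deep zone), the RAFF and spin-lock variants
less so, T1 not at all. Orientation-sensitive parameters track the
collagen-network anisotropy measured by qPLM (r ≈ 0.9), while T1 is
uncorrelated — its residual profile is pure noise.

The `examples/` directory walks through each stage separately
(phantom construction, map fitting, profiling, MR and PLM anisotropy,
full study); each script prints the numbers it computes and what they
mean. A thin CLI mirrors the stages
(`relaxaniso simulate|fit|profile|aniso|plm|correlate|run-all`) on
NIfTI/TIFF/CSV files so measured data can be substituted for the
phantom at any stage.

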