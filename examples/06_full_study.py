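"""The full study in one call: four replicate specimens, all parameter
variants, orientation sweep, qPLM comparison and Fisher-z-averaged
correlations.

Writes the report bundle (summary, zone statistics, tidy profiles,
manifest) to ./study_report.
"""

from relaxaniso import run_all

result = run_all({"seed": 1, "n_samples": 2,
                  "parameter_kinds": ["T2", "RAFF2", "CWT1rho_500", "T1"]},
                 outdir="study_report")

cols = ["parameter_kind", "anisotropy_mean_pct", "r_plm_anisotropy"]
print(result["summary"][cols].round(2).to_string(index=False))
print(f"\nconfig hash: {result['manifest']['config_sha256'][:12]}...")

# Expected output: kinds ordered by deep-zone anisotropy (T2 highest,
# T1 near zero); orientation-sensitive kinds correlate strongly
# (r > 0.8) with the qPLM collagen anisotropy while T1 does not.
# Rerunning with the same seed reproduces the CSVs byte for byte.
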