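"""Michelson orientation-anisotropy of T2 as a function of depth.

Relaxation-time profiles from the seven sample orientations are
converted to rates and reduced per depth point to the Michelson
contrast A = (Rmax - Rmin)/(Rmax + Rmin).
"""

import numpy as np

from relaxaniso import (
    PhantomSpec,
    deep_zone_anisotropy,
    default_schedules,
    extract_profile,
    fit_map,
    generate_series,
    mr_anisotropy_profile,
    normalize_depth,
)

spec = PhantomSpec(seed=1)
profiles = []
for phi in (0.0, 15.0, 30.0, 45.0, 60.0, 75.0, 90.0):
    rmap = fit_map(generate_series(spec, default_schedules()["T2"], phi))
    raw = extract_profile(rmap.times_ms, rmap.mask, valid=rmap.converged)
    profiles.append(normalize_depth(raw, 100, parameter_kind="T2", orientation_deg=phi))

ap = mr_anisotropy_profile(profiles)
d_min = ap.depth[np.nanargmin(ap.values)]
print(f"anisotropy minimum {np.nanmin(ap.values):.2f} at depth {d_min:.2f} "
      "(transitional zone)")
print(f"deep-zone (40-80%) anisotropy: {deep_zone_anisotropy(ap):.1f}%")

# Expected output: the profile dips in the transitional zone, where
# fibre-orientation dispersion flattens the angular dependence, and the
# deep-zone bulk value sits near 80% for T2.
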