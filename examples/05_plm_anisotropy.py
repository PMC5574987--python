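"""qPLM analysis: entropy-filter collagen anisotropy and depth profiles.

The orientation-angle map is quantized to 256 bins over [0, 180) and a
5x5 Shannon-entropy filter applied; anisotropy is 1/(entropy + 1), so
uniform fibre orientation gives 1 and disordered tissue approaches 0.
"""

import numpy as np

from relaxaniso import PhantomSpec, generate_plm_maps, plm_profiles
from relaxaniso.plm import entropy_filter, plm_anisotropy

spec = PhantomSpec(seed=1)
maps = generate_plm_maps(spec)

entropy = entropy_filter(maps.orientation)
aniso = plm_anisotropy(entropy)
cart = spec.cartilage_rows
print(f"entropy range in tissue: {entropy[cart].min():.2f}-"
      f"{entropy[cart].max():.2f} bits")

profs = plm_profiles(maps)
a = profs["anisotropy"]
print(f"PLM anisotropy: minimum {np.nanmin(a.values):.3f} at depth "
      f"{a.depth[np.nanargmin(a.values)]:.2f}")
ori = profs["orientation"]
print(f"orientation profile: {ori.values[0]:.0f} deg at the surface, "
      f"{ori.values[-1]:.0f} deg at the bone interface")

# Expected output: entropy peaks (anisotropy dips) in the transitional
# zone where the local fibre-angle dispersion is largest; the
# orientation profile arches from ~90 deg at the surface to ~0 deg deep.
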