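"""Build the synthetic magic-angle cartilage phantom and inspect it.

The phantom is a layered slab: collagen fibres lie parallel to the
articular surface in the superficial zone, arch through the
transitional zone and run along the surface normal in the deep (radial)
zone.  Transverse relaxation rates carry a residual-dipolar term
proportional to (3 cos^2 theta - 1)^2 that vanishes at the magic angle.
"""

import numpy as np

from relaxaniso import (
    PhantomSpec,
    default_schedules,
    dipolar_factor,
    fibre_angle_profile,
    generate_series,
    magic_angle_deg,
    true_rate,
)

spec = PhantomSpec(seed=1)

print(f"magic angle: {magic_angle_deg():.4f} deg  "
      f"(dipolar factor there: {dipolar_factor(magic_angle_deg()):.2e})")

for d in (0.0, 0.15, 0.25, 0.5, 1.0):
    print(f"depth {d:.2f}: fibre angle {fibre_angle_profile(d, spec):5.1f} deg, "
          f"T2 rate at 0 deg orientation {true_rate(d, 0.0, 'T2', spec):6.1f} /s")

series = generate_series(spec, default_schedules()["T2"], sample_orientation_deg=0.0)
fg = series.data[0][series.mask].mean()
sigma = series.data[:, series.background_roi].mean() / np.sqrt(np.pi / 2)
print(f"measured SNR of the generated T2 series: {fg / sigma:.1f} "
      f"(requested {spec.snr:g})")

# Expected output: the fibre angle falls from 90 deg at the surface to
# 0 deg past 30% depth; the T2 rate at 0 deg orientation is largest in
# the deep zone where the fibres align with B0; the measured SNR sits
# near the requested 40.
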