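"""Fit a pixel-wise T2 map and compare it with the ground truth.

T2 decays are fitted per pixel with a two-parameter monoexponential
after quadrature noise-floor subtraction (sigma estimated from the
noise-only background ROI).
"""

import numpy as np

from relaxaniso import (
    PhantomSpec,
    default_schedules,
    effective_time_ms,
    estimate_noise_sigma,
    fit_map,
    generate_series,
)

spec = PhantomSpec(seed=1)
series = generate_series(spec, default_schedules()["T2"], sample_orientation_deg=90.0)

print(f"estimated noise sigma: {estimate_noise_sigma(series):.1f} signal units")

rmap = fit_map(series)
conv = rmap.converged[rmap.mask].mean()
print(f"converged pixels: {100 * conv:.1f}%")

truth = effective_time_ms(spec.depth_of_rows(), 90.0, "T2", spec)
est = rmap.times_ms[spec.cartilage_rows, :]
rel = np.abs(est - truth[:, None]) / truth[:, None]
print(f"map-median relative T2 error: {100 * np.median(rel):.2f}%")
print(f"T2 at mid depth: fitted {np.nanmedian(est[24]):.1f} ms, "
      f"true {truth[24]:.1f} ms")

# Expected output: >99% convergence and a map-median error of a few
# percent at the phantom's SNR of 40.
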