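"""Depth-wise profiling: from a fitted map to zone statistics.

Profiles are the per-row mean over a 1.75 mm centre band, normalized so
depth 0 is the articular surface and 1 the cartilage-bone interface,
then summarised per structural zone (SZ / TZ / RZ).
"""

from relaxaniso import (
    PhantomSpec,
    default_schedules,
    extract_profile,
    fit_map,
    generate_series,
    normalize_depth,
    zone_stats,
)

spec = PhantomSpec(seed=1)
profiles = []
for phi in (0.0, 30.0, 60.0, 90.0):
    rmap = fit_map(generate_series(spec, default_schedules()["T2"], phi))
    raw = extract_profile(rmap.times_ms, rmap.mask, valid=rmap.converged)
    profiles.append(normalize_depth(raw, 100, parameter_kind="T2", orientation_deg=phi))

print("T2 zone statistics over 4 orientations (ms):")
print(zone_stats(profiles).round(1).to_string())

# Expected output: deep-zone (RZ) T2 shows the widest min/max range
# across orientations -- the magic-angle effect is strongest where the
# fibres are most ordered; the transitional zone varies least.
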