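"""Quantify GLY77 backbone stability via phi-dihedral circular statistics.

The phi torsion C(76)-N(77)-CA(77)-C(77) is recomputed from the rendered
backbone coordinates of all four subunits; circular variance (1 minus the
mean resultant length) measures how tightly the angle is held.  The axial
field stabilises GLY77; without a field or at theta = 90 deg the angle
wanders over a bimodal range.
"""

from dataclasses import replace

from kperm import (
    circular_summary,
    default_geometry,
    get_preset,
    phi_series,
    render_frames,
    simulate_timeline,
)
import numpy as np

geom = default_geometry()

print(f"{'scenario':<10} {'circ. mean':>10} {'R_bar':>7} {'circ. var':>10}")
for name in ("theta0", "theta45", "theta90", "no_field"):
    params = replace(get_preset(name), duration_us=0.1, expected_events=0)
    timeline = simulate_timeline(params, seed=11)
    traj = render_frames(timeline, geom, frame_interval=0.5, seed=11)
    angles = np.concatenate([phi_series(traj, "GLY77", ch).angles for ch in "ABCD"])
    s = circular_summary(angles)
    print(f"{name:<10} {s.mean_deg:>9.1f}  {s.resultant_length:>7.3f} {s.variance:>10.3f}")
# Low circular variance = conformationally stable residue.  The ordering
# theta0 < theta45 < (theta90, no_field) tracks the ion flux ordering: a
# distorted GLY77 carbonyl cage is what slows permeation.
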