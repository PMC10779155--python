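# kperm

Trajectory analysis for K⁺ permeation through the KcsA selectivity filter
under an oscillating terahertz electric field — with a calibrated synthetic
kinetic generator standing in for the microsecond molecular-dynamics
trajectories such studies produce.

## The problem

The selectivity filter (SF) of the tetrameric KcsA channel is the conserved
T-V-G-Y-G segment whose backbone carbonyl oxygens form five stacked K⁺
binding sites, S4 (innermost, cavity side) through S0 (extracellular).
A 51.87 THz field of amplitude 0.4 V/nm, tilted by an angle θ from the pore
axis within the XOZ plane, modulates conduction: flux is maximal when the
field is axial (θ = 0°) and minimal when it is perpendicular (θ = 90°).
Dissecting *why* requires a set of standard trajectory computations that
this package implements as a tested, reusable pipeline:

- **Permeation counting and current conversion** — a per-ion finite-state
  detector counts complete CAVITY → S4…S0 → EXTRACELLULAR traversals; the
  count N over time T converts to flux N/T and single-channel current
  I = N·e/T (e the elementary charge).
- **Site occupancy and density** — frame-wise classification of each site
  as ion/water/empty, axial density profiles, and per-site integrated
  occupancies.
- **Exotic-state probability** — the fraction of frames (census every 5 ns)
  in which K⁺ occupies exactly the (S4,S3) or (S3,S2) pair, a trapped
  configuration associated with slowed conduction.
- **Knock-on mechanism classification** — direct (Coulomb) knock-on with
  adjacent ions in contact versus soft knock-on with water interleaved
  (K–W–K patterns), decided per detected event.
- **GLY77 φ-dihedral stability** — backbone torsions C(i−1)–N–CA–C
  recomputed from coordinates and summarised with circular statistics;
  circular variance 1 − R̄ measures conformational stability of the filter
  residues THR75…GLY79 on all four subunits.

Because the underlying MD trajectories are not deposited anywhere, the
package ships a first-class synthetic generator (`kperm.synthetic`) whose
presets are calibrated to the study's printed summary statistics: 587
events per 3.2 μs at θ = 0°, 374 at θ = 90°, a 23.6 pA no-field current,
a 31% exotic-state probability at θ = 90° (≤ 15% otherwise), and
per-residue von Mises φ distributions. Real MD output (PDB/GRO + XTC/DCD)
can be analysed through the MDAnalysis-backed adapter in `kperm.io`.

## Worked example

```python
from kperm import (default_geometry, get_preset, simulate_timeline,
                   render_frames, detect_events, current_pA, exotic_fraction)

geom = default_geometry()
params = get_preset("theta90")              # perpendicular field scenario
timeline = simulate_timeline(params, seed=3)     # ground-truth kinetics
traj = render_frames(timeline, geom, frame_interval=5.0, seed=3)

rep = exotic_fraction(traj, geom, interval=5.0)
print(rep.exotic_fraction)
```

Running `python examples/02_exotic_states.py` (which does the above for
both field orientations) prints:

```
theta90: 641 census frames every 5.0 ns
  P(S4,S3 pair)  = 0.147
  P(S3,S2 pair)  = 0.165
  P(exotic)      = 0.312   (generator time fraction 0.307)
theta0: 641 census frames every 5.0 ns
  P(S4,S3 pair)  = 0.042
  P(S3,S2 pair)  = 0.055
  P(exotic)      = 0.097   (generator time fraction 0.103)
```

i.e. with the perpendicular field the filter spends ~31% of census frames
trapped in the two exotic pair states, against ~10% for the axial field —
the signature that accompanies the drop from 587 to 374 permeations per
3.2 μs. The other scripts in `examples/` demonstrate event counting and
current conversion, mechanism classification and density profiles, GLY77
dihedral stability, and a full θ sweep; each prints the numbers it
computes with a closing comment on what they mean.

A thin CLI mirrors the library:

```bash
kperm run --config scenario.yaml      # generate -> analyse -> report
kperm flux --traj run.kpf --out events.tsv
kperm states --traj run.kpf --interval 5
kperm dihedrals --traj run.kpf --residues GLY77
```

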