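# Methods

This note records the models, calibrations and numerical choices behind
`kperm`, in the order a user meets them: filter geometry, the synthetic
kinetic generator, the analysis operations, and known limitations.

## Filter geometry and conventions

The selectivity filter is modelled as six axial oxygen planes bounding five
sites S4…S0. The default geometry places the planes at z = 0.00, 0.31,
0.62, …, 1.55 nm — 0.31 nm is a typical carbonyl-plane spacing in K⁺
channel filters — with the pore axis along +z and intracellular →
extracellular increasing z. No published coordinate set fixes the plane
positions used for site censuses, so the default is an idealisation;
`SFGeometry` is fully configurable and serialisable, and planes measured
from a real structure can be substituted without touching any analysis.

Site assignment is by half-open intervals closed below (`z ∈ [plane_k,
plane_{k+1}) → site k`), making boundary ties deterministic and
order-independent; z below plane 0 is CAVITY, at or above plane 5
EXTRACELLULAR. Units are fixed package-wide: nm, ns (ps only inside the
field oscillation), degrees, pA.

The applied field is `E(t) = A·cos(2πft + φ₀)·(sin θ, 0, cos θ)` with A in
V/nm and f in THz — a single-frequency plane wave confined to the XOZ
plane, tilted θ from the pore axis. The field is carried as scenario
metadata and shapes trajectories only through the per-angle presets; no
electrostatics is computed (the charge-imbalance/constant-field machinery
of the original MD setup is out of scope by design).

## The synthetic generator

### Two-regime kinetics

Ground truth is an alternating-renewal ("semi-Markov") process with a
NORMAL conduction regime interrupted by trapped **exotic** episodes in
which K⁺ occupies exactly the (S4,S3) or (S3,S2) pair (equal split — only
their combined probability is known). Episode dwells are exponential with
mean τ = 5 ns; the dwell is a free parameter (no measured value exists) and
5 ns was chosen so that episodes are long against the 50 ps frame grid but
short against the 5 ns census interval. Episodes arrive within normal time
as a Poisson process of rate f/((1−f)τ), which makes the stationary exotic
time-fraction equal the preset value f; the initial regime is drawn from
the stationary law, so the realised fraction is unbiased at every horizon.
Episodes closer than 1.2 ns are fused — with the later dwell shifted flush
against the earlier one, conserving total exotic time exactly — so that
boundary transients (below) can never collide.

### Event counts

Permeation is suppressed during exotic episodes ("trapped" is taken
literally; partial suppression would need a parameter nobody has measured).
The total number of complete outward permeations is drawn
N ~ Poisson(expected_events) and completion times are placed uniformly over
the usable normal time with a refractory spacing of 1.05 ns between
completions and a 1.2 ns keep-out from segment boundaries. Placing a
pre-drawn Poisson count, rather than running a fixed-rate Poisson process
inside the *realised* normal time, is deliberate: the realised normal time
fluctuates seed-to-seed, and conditioning a fixed rate on it would
overdisperse the unconditional count (variance/mean up to ~1.8 at the
θ = 90° parameters) — the pre-drawn count keeps the mean exact and the
count exactly Poisson. The spacing exists so that rendered event
choreographies never overlap; it biases nothing because the count is fixed
before placement. Each event is labelled a direct knock-on with the
preset's probability, else soft.

### Rendering and the knock-on choreography

Rendering maps the timeline onto per-frame coordinates. Time is
discretised into 75 ps choreography phases; every particle movement is a
single-site step lasting one phase, so at frame spacings of 50 ps or finer
no tracked ion ever skips a site between adjacent frames. The one
exception is bookkeeping: an ion that has exited is recycled from
EXTRACELLULAR back to the CAVITY pool by a direct teleport between event
windows — never through the filter, so it can neither skip sites *inside*
the SF nor fire the inward-event detector.

Around each completion time t the generator plays a seven-phase
choreography: the transiting ion walks CAVITY → S4 → S3 → S2 → S1 → S0 →
EXTRACELLULAR (exit at t) while a companion ion enters behind it and
returns to the cavity, so frames show the canonical two-ion knock-on
configurations (S4,S2) → (S3,S1) → (S2,S0). For soft events two water
oxygens are interleaved so that every multi-ion frame in the event span
shows K–W–K patterning; direct events place no water anywhere in their
span. A three-ion configuration such as (S4,S3,S1) is not produced — a
two-ion choreography cannot form it — and, crucially, no NORMAL-regime
frame ever shows K occupying exactly {S4,S3} or {S3,S2}: those patterns
are the exotic-state signature and appear only inside their episodes.

During NORMAL regime the filter also holds a resting occupancy: K⁺ at S4
and S2 (the stable conduction ground state) for every scenario except
θ = 90°, whose destabilised filter holds only the S4 ion. This is what
carries the observed density ordering — S2 occupancy lowest at θ = 90°,
highest without a field — because the resting pattern, not the brief event
transits, dominates time-averaged density. Resting ions step aside into
the cavity (single-site walks, staggered to avoid the exotic signatures)
around every event window and every exotic episode, so they never collide
with a choreography and never pollute the exotic census. Exotic residents
hold their pair for *exactly* the drawn episode window, with walk-in/out
transients placed outside it; folding transients into the window would
bias the measured 5 ns census low by about 3% absolute at θ = 90°.

Occupied positions are the site's axial midpoint plus isotropic Gaussian
jitter (σ = 0.05 nm, truncated so the site label is preserved; a σ of half
the site height or more is rejected as a configuration error).

### Backbones

Four subunit backbones (chains A–D, residues 74–80, atoms N/CA/C/O) are
rebuilt every frame by NeRF-style torsion-to-Cartesian extension with
standard peptide internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å; C–N–CA 121.7°, N–CA–C 111.2°, CA–C–N 116.2°; ω = 180°, ψ fixed at
135°). Only φ is stochastic, drawn i.i.d. per frame, residue and chain
from the preset's von Mises mixtures; chains are then placed by rigid
rotation/translation around the pore, which leaves every torsion intact.
The builder is exact: recomputing φ from the built coordinates reproduces
the sampled value to ~10⁻¹³ degrees, and the test suite asserts 10⁻⁶.

### Calibration

Per-scenario presets (3.2 μs each):

| scenario | events | exotic f | direct prob | GLY77 φ |
|----------|-------:|---------:|------------:|---------|
| theta0   | 587    | 0.10     | 0.95        | vM(−80°, κ=40) |
| theta30  | 550    | 0.10     | 0.90        | vM(−80°, κ=15) |
| theta45  | 520    | 0.10     | 0.90        | vM(−80°, κ=15) |
| theta60  | 460    | 0.10     | 0.90        | vM(−80°, κ=15) |
| theta90  | 374    | 0.31     | 0.69        | 0.6·vM(−80°, 8) + 0.4·vM(70°, 4) |
| no_field | 471    | 0.12     | 0.90        | same mixture as theta90 |

The θ = 0° and θ = 90° event counts and the θ = 90° exotic fraction are the
measured anchors; the no-field count is the one whose current over 3.2 μs
is 23.6 pA (471 × e / 3.2 μs = 23.58 pA). The θ = 30/45/60° counts are
monotone interpolations — the intermediate values were never printed — and
are documented package constants, as are their exotic fractions (0.10,
within the reported ≤ 0.15 band). THR75/VAL76 φ distributions are
identical high-concentration von Mises across all scenarios (the field
angle does not touch the S4/S3 cages); TYR78/GLY79 broaden (κ 40 → 12) in
the two unstable conditions. The κ values are package choices made once to
reproduce the qualitative variance ordering θ0 < θ30/45/60 < {θ90,
no-field}; no numeric widths are available to fit.

Note an internal tension in the source numbers: 587 events per 3.2 μs is
1.25× the 471-event no-field baseline implied by 23.6 pA, while the text
separately quotes a 1.8× flux enhancement. Both cannot hold; the presets
honour the printed counts and current, and the acceptance suite asserts
the ≈1.25 ratio rather than 1.8.

### Seeding

One master seed drives everything: the timeline uses streams spawned under
`spawn_key=(1,)`, rendering under `(2,)`, so timeline and coordinates are
independently reproducible from the same integer. All derived seeds stay
below 2³¹.

## Analysis operations

**Event detection** is a per-ion finite-state tracker: entering the SF
from the cavity arms it, reaching the extracellular side while armed emits
an outward event, returning to the cavity disarms it (inward symmetric).
An event therefore requires a *complete* traversal; brief S0 recrossings
cannot double-count. Ions already inside the filter at the first frame are
unarmed. Duration for flux/current is taken from the frame time span, with
a warning if metadata disagrees. On generator output the detector
reproduces the ground-truth event log exactly at 50 ps sampling, and the
count is invariant to oversampling; a warning fires when the median
inter-frame site displacement of any ion exceeds one site.

**Occupancy classification** labels a site K if ≥ 1 ion maps there (two
ions in one cage is reported as an anomaly, not an error), else W if a
water oxygen maps there, else EMPTY. The exotic flags use the strict
reading — K at exactly the named pair and no other SF site — with a
permissive variant (pair occupied, other sites ignored) behind a flag,
since the definition is not disambiguated anywhere. The exotic census
classifies the frames nearest t = 0, Δ, 2Δ, … with Δ = 5 ns by default.

**Mechanism classification** inspects a detected event's frames: no K–W–K
frame at all → direct; at least half of the multi-ion frames K–W–K → soft;
otherwise mixed (events under two frames are reported "insufficient").
The 50% threshold is a package decision — no quantitative rule exists —
and blind labels agree with generator ground truth on 100% of events in
the test scenarios.

**Density profiles** subdivide each site into bins as close to the
requested width (default 0.02 nm) as divides the site evenly, so site
boundaries are always bin edges and the per-site integrals partition the
total exactly: their sum equals the mean number of SF-resident ions per
frame to machine precision.

**Dihedrals** use the two-plane-normal atan2 torsion in (−180°, 180°]
(IUPAC sign), raising on collinear geometry. The signed torsion is
invariant under rigid motion *and* under chain reversal (reversal flips
both plane normals and the central bond, leaving both atan2 arguments
unchanged); a mirror reflection negates it. Stability is summarised as
circular variance 1 − R̄ — the study speaks only of angles "maintained in
a limited range", so a continuous summary was chosen over any threshold
rule — with per-chain series kept separate (the filter is four-fold
symmetric) and pooling left to the caller. Histograms default to 5° bins.

## Problem sizes

Full-scale runs — 3.2 μs at 50 ps (64 001 frames, ~120 atoms) — are used
for the acceptance suite and script (10 seeds per scenario, ~3 s per seed);
module tests use 0.05–0.4 μs renders with event counts scaled pro rata,
which preserves every structural property of the generator. Statistical
invariants are checked at 200–500 timeline draws (timeline simulation
needs no rendering and runs in milliseconds).

## Known limitations

- The generator reproduces the *statistics* the analyses consume, not
  channel physics: no force field, no water dynamics (water oxygens are
  placeholders at water-labelled sites), no membrane, no voltage. Field
  orientation enters only through preset parameters; passing tests show
  the pipeline recovers what the generator encodes, not that the field
  mechanism itself is simulated.
- Transit dwell (75 ps per site) and the resting patterns are stylised;
  real dwell-time distributions, multi-ion queueing and cavity kinetics
  are not emulated. Density profiles are therefore faithful in ordering
  but not in fine shape.
- ψ/ω are frozen, so Ramachandran coupling and any ψ response to the
  field are invisible by construction; only φ distributions are modelled.
- The default plane spacing (and hence absolute z positions in density
  output) is idealised; analyses of real trajectories should supply a
  geometry measured from the structure at hand, via the adapter's
  recentering option where needed.
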