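"""Synthetic kinetic trajectory generator.

Generates ground-truth occupancy timelines and coordinate-level trajectories
with the statistical structure the analysis pipeline assumes:

* a two-regime alternating-renewal process: NORMAL conduction interrupted by
  trapped "exotic" episodes in which K+ occupies exactly the (S4,S3) or
  (S3,S2) site pair and permeation is suppressed;
* complete outward permeation events at a calibrated expected count, each
  labelled direct or soft knock-on;
* per-frame coordinates: ions/waters at jittered site midpoints following a
  short knock-on choreography around every event, and four subunit backbones
  (residues 74-80, atoms N/CA/C/O) built by torsion-to-Cartesian chain
  extension with phi drawn from the preset circular distributions.

Timing is discretised internally into choreography phases of
``PHASE_NS`` = 0.075 ns: every single-site move lasts one phase, so at frame
spacings of 50 ps or finer no tracked ion ever skips a site between adjacent
frames (the one exception is the bookkeeping teleport that recycles an exited
ion from EXTRACELLULAR back to the CAVITY pool between events).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .chain import BackboneSpec, build_chain
from .presets import PresetParams, VonMisesMixture, derive_normal_rate
from .sf_model import (
    CODE_CAVITY,
    CODE_EXTRACELLULAR,
    SFGeometry,
    default_geometry,
)
from .trajectory import (
    ROLE_BACKBONE,
    ROLE_ION,
    ROLE_WATER,
    Trajectory,
    make_topology,
)

__all__ = [
    "REGIME_NORMAL",
    "REGIME_EXOTIC_S4S3",
    "REGIME_EXOTIC_S3S2",
    "Segment",
    "GroundTruthEvent",
    "OccupancyTimeline",
    "simulate_timeline",
    "render_frames",
    "PHASE_NS",
]

REGIME_NORMAL = "NORMAL"
REGIME_EXOTIC_S4S3 = "EXOTIC_S4S3"
REGIME_EXOTIC_S3S2 = "EXOTIC_S3S2"

MECH_DIRECT = "direct"
MECH_SOFT = "soft"

#: Duration of one choreography phase (ns); each single-site ion move spans
#: one phase, so phases are longer than the densest supported frame spacing.
PHASE_NS = 0.075
#: Transit window before an event's completion time (5 site dwells).
_EVENT_PRE = 5 * PHASE_NS
#: Minimum spacing between successive completion times; the full event
#: choreography (resting-ion dodge out, transit, companion wind-down,
#: resting-ion dodge back in) spans 13 phases, so consecutive windows never
#: overlap.
MIN_EVENT_GAP = 14 * PHASE_NS
#: Keep-out margin between completion times and segment boundaries (covers
#: the event window plus resting-ion and exotic walk-in/out transients).
_SEGMENT_MARGIN = 16 * PHASE_NS
#: Exotic episodes closer than this are merged so their boundary transients
#: cannot collide.
_MERGE_GAP = 1.2

# Site-content alphabet used in segment patterns.
K, W, EMPTY = "K", "W", "EMPTY"

_EXOTIC_PATTERNS = {
    REGIME_EXOTIC_S4S3: (K, K, EMPTY, EMPTY, EMPTY),
    REGIME_EXOTIC_S3S2: (EMPTY, K, K, EMPTY, EMPTY),
}

# Internal placement codes: 0 CAVITY, 1..5 = S4..S0, 6 EXTRACELLULAR,
# -1 parked out of play (waters between appearances).
_PARKED = -1


@dataclass(frozen=True)
class Segment:
    """Maximal run of constant regime with its per-site occupancy pattern
    (ordered S4..S0)."""

    t_start: float
    t_end: float
    regime: str
    pattern: tuple[str, str, str, str, str]

    @property
    def is_exotic(self) -> bool:
        return self.regime != REGIME_NORMAL


@dataclass(frozen=True)
class GroundTruthEvent:
    """One complete outward permeation in the generator's event log."""

    index: int
    t_enter: float  # ns; transiting ion first reaches S4
    t_exit: float  # ns; ion crosses into the extracellular region
    mechanism: str  # "direct" or "soft"


@dataclass
class OccupancyTimeline:
    """Piecewise ground truth: regimes, occupancy patterns, event log."""

    duration: float  # ns
    segments: list[Segment]
    events: list[GroundTruthEvent]
    seed: int
    params: PresetParams

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("timeline needs at least one segment")
        t = 0.0
        for seg in self.segments:
            if not math.isclose(seg.t_start, t, abs_tol=1e-9):
                raise ValueError("segments must be contiguous from t=0")
            if seg.t_end <= seg.t_start:
                raise ValueError("segments must have positive length")
            t = seg.t_end
        if not math.isclose(t, self.duration, abs_tol=1e-9):
            raise ValueError("segments must cover [0, duration]")
        for ev in self.events:
            seg = self.segment_at(ev.t_exit)
            if seg.is_exotic:
                raise ValueError("event completions cannot lie in exotic segments")

    def segment_at(self, t: float) -> Segment:
        for seg in self.segments:
            if seg.t_start <= t < seg.t_end or (t == self.duration and seg.t_end == t):
                return seg
        raise ValueError(f"time {t} outside [0, {self.duration}]")

    @property
    def exotic_time_fraction(self) -> float:
        """Exact realised time fraction spent in either exotic regime."""
        ex = sum(s.t_end - s.t_start for s in self.segments if s.is_exotic)
        return ex / self.duration

    def n_events(self) -> int:
        return len(self.events)


def simulate_timeline(params: PresetParams, seed: int) -> OccupancyTimeline:
    """Draw one ground-truth timeline for the given scenario parameters.

    Regime structure is an alternating-renewal process started from its
    stationary law: exotic episodes have exponential dwell (mean
    ``exotic_dwell_mean``) and arrive within normal time as a Poisson process
    whose rate makes the stationary exotic time-fraction equal
    ``exotic_fraction``.  The total number of complete permeations is drawn
    Poisson with mean ``expected_events`` and completion times are spread
    uniformly over normal time, with a short refractory spacing
    (:data:`MIN_EVENT_GAP`) so rendered knock-on choreographies never
    overlap.  Same params + same seed always yields an identical timeline.
    """
    if params.duration_ns <= 0:
        raise ValueError("duration must be positive")
    # spawn_key=(1,) reserves this stream family for the timeline; rendering
    # uses (2,), so one master seed drives both without overlap.
    ss = np.random.SeedSequence(seed, spawn_key=(1,))
    rng_regime, rng_events, rng_mech = (np.random.default_rng(s) for s in ss.spawn(3))

    T = params.duration_ns
    f = params.exotic_fraction
    tau = params.exotic_dwell_mean

    episodes: list[list[float]] = []
    if f > 0:
        rate = f / ((1.0 - f) * tau)  # exotic arrivals per ns of normal time
        t = 0.0
        in_exotic = bool(rng_regime.random() < f)  # stationary initial regime
        while t < T:
            if in_exotic:
                dwell = rng_regime.exponential(tau)
                episodes.append([t, min(t + dwell, T)])
                t += dwell
            else:
                t += rng_regime.exponential(1.0 / rate)
            in_exotic = not in_exotic
        # Episodes separated by less than _MERGE_GAP are fused so boundary
        # transients never collide; the later dwell is shifted flush against
        # the earlier one, conserving total exotic time exactly.
        merged: list[list[float]] = []
        for ep in episodes:
            if merged and ep[0] - merged[-1][1] < _MERGE_GAP:
                merged[-1][1] += ep[1] - ep[0]
            else:
                merged.append(ep)
        episodes = [ep for ep in merged if min(ep[1], T) > ep[0]]
        for ep in episodes:
            ep[1] = min(ep[1], T)

    resting = tuple(params.normal_pattern)
    segments: list[Segment] = []
    cursor = 0.0
    for a, b in episodes:
        if a > cursor:
            segments.append(Segment(cursor, a, REGIME_NORMAL, resting))
        regime = (
            REGIME_EXOTIC_S4S3
            if rng_regime.random() < 0.5
            else REGIME_EXOTIC_S3S2
        )
        segments.append(Segment(a, b, regime, _EXOTIC_PATTERNS[regime]))
        cursor = b
    if cursor < T:
        segments.append(Segment(cursor, T, REGIME_NORMAL, resting))

    # --- permeation completions ------------------------------------------
    n_events = int(rng_events.poisson(params.expected_events))
    usable: list[tuple[float, float]] = []
    for seg in segments:
        if seg.is_exotic:
            continue
        a = seg.t_start + _SEGMENT_MARGIN
        b = seg.t_end - _SEGMENT_MARGIN
        if b > a:
            usable.append((a, b))
    total_usable = sum(b - a for a, b in usable)
    if n_events > 0 and total_usable < n_events * MIN_EVENT_GAP * 2:
        raise ValueError(
            "normal-regime time is too fragmented to place the requested "
            f"{n_events} events; increase duration or lower expected_events"
        )

    starts = np.array([a for a, _ in usable])
    lengths = np.array([b - a for a, b in usable])
    cum = np.concatenate([[0.0], np.cumsum(lengths)])

    placed: list[float] = []
    attempts = 0
    while len(placed) < n_events:
        attempts += 1
        if attempts > 1000 * max(n_events, 1):
            raise RuntimeError("failed to place events with the required spacing")
        u = rng_events.random() * total_usable
        k = int(np.searchsorted(cum, u, side="right") - 1)
        t = starts[k] + (u - cum[k])
        if all(abs(t - s) >= MIN_EVENT_GAP for s in placed):
            placed.append(t)
    placed.sort()

    is_direct = rng_mech.random(n_events) < params.mechanism_direct_prob
    events = [
        GroundTruthEvent(
            index=i,
            t_enter=t - _EVENT_PRE,
            t_exit=t,
            mechanism=MECH_DIRECT if d else MECH_SOFT,
        )
        for i, (t, d) in enumerate(zip(placed, is_direct))
    ]

    return OccupancyTimeline(
        duration=T, segments=segments, events=events, seed=seed, params=params
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


class _Schedule:
    """Piecewise-constant placement code per atom: list of (time, code)."""

    def __init__(self, initial: int):
        self.steps: list[tuple[float, int]] = [(-math.inf, initial)]

    def add(self, time: float, code: int) -> None:
        self.steps.append((max(time, 0.0), code))

    def codes_at(self, times: np.ndarray) -> np.ndarray:
        steps = sorted(self.steps)
        t = np.array([s[0] for s in steps])
        c = np.array([s[1] for s in steps], dtype=np.int8)
        idx = np.searchsorted(t, times, side="right") - 1
        return c[idx]


class _Pool:
    """Reusable atom slots with busy-until bookkeeping."""

    def __init__(self, initial_code: int):
        self.initial = initial_code
        self.slots: list[_Schedule] = []
        self.busy_until: list[float] = []

    def acquire(self, start: float, until: float) -> _Schedule:
        for i, b in enumerate(self.busy_until):
            if b <= start:
                self.busy_until[i] = until
                return self.slots[i]
        sched = _Schedule(self.initial)
        self.slots.append(sched)
        self.busy_until.append(until)
        return sched


def _walk_in(sched: _Schedule, target: int, arrival: float) -> None:
    """Single-site upward walk CAVITY -> ... -> target, arriving on time."""
    for code in range(1, target + 1):
        sched.add(arrival - (target - code) * PHASE_NS, code)


def _walk_out(sched: _Schedule, target: int, departure: float) -> None:
    """Single-site downward walk target -> ... -> CAVITY starting at departure."""
    for k, code in enumerate(range(target - 1, -1, -1)):
        sched.add(departure + k * PHASE_NS, code)


def _event_choreography(
    ev: GroundTruthEvent,
    ion_pool: _Pool,
    water_pool: _Pool,
) -> None:
    """Schedule the knock-on choreography of one permeation event.

    The transiting ion walks CAVITY->S4->S3->S2->S1->S0->EXTRACELLULAR,
    exiting at ``t_exit``; a companion ion enters behind it and returns to
    the cavity, so frames show the canonical two-ion knock-on configurations
    (S4,S2) -> (S3,S1) -> (S2,S0).  Soft events interleave water oxygens so
    every multi-ion frame shows K-W-K patterning; direct events place no
    water anywhere in the event span.
    """
    p = PHASE_NS
    t = ev.t_exit
    c = ion_pool.acquire(t - 5 * p, t + 3 * p)
    d = ion_pool.acquire(t - 5 * p, t + 3 * p)

    for k, code in enumerate((1, 2, 3, 4, 5)):  # S4..S0
        c.add(t - (5 - k) * p, code)
    c.add(t, CODE_EXTRACELLULAR)
    c.add(t + 2 * p, CODE_CAVITY)  # recycle teleport, never through the SF

    d.add(t - 3 * p, 1)  # S4
    d.add(t - 2 * p, 2)  # S3
    d.add(t - 1 * p, 3)  # S2
    d.add(t, 2)  # back to S3
    d.add(t + 1 * p, 1)  # S4
    d.add(t + 2 * p, CODE_CAVITY)

    if ev.mechanism == MECH_SOFT:
        w1 = water_pool.acquire(t - 4 * p, t + p)
        w2 = water_pool.acquire(t - 4 * p, t + p)
        w1.add(t - 4 * p, 1)  # S4
        w1.add(t - 3 * p, 2)  # S3
        w1.add(t - 2 * p, 3)  # S2
        w1.add(t - 1 * p, 4)  # S1
        w1.add(t, _PARKED)
        w2.add(t - 2 * p, 1)  # S4
        w2.add(t - 1 * p, _PARKED)


def _background_walkers(
    timeline: OccupancyTimeline,
    bg_ions: dict[int, _Schedule],
    bg_waters: dict[int, _Schedule],
) -> None:
    """Schedule per-site background occupants realising segment patterns.

    K occupants walk in through the lower sites and out again, staggered so
    that no transient frame shows K occupying exactly {S4,S3} or {S3,S2}
    outside an exotic segment (those site pairs are the exotic-state
    signature and must appear only inside their episodes).  Exotic residents
    hold their pair for exactly the episode window, with walk transients
    outside it; NORMAL resting ions keep clear of the episode and event
    choreographies, dodging into the cavity around every permeation window.
    """
    p = PHASE_NS
    duration = timeline.duration
    for seg in timeline.segments:
        k_sites = sorted(i + 1 for i, c in enumerate(seg.pattern) if c == K)
        w_sites = [i + 1 for i, c in enumerate(seg.pattern) if c == W]
        n = len(k_sites)
        for rank, code in enumerate(k_sites):
            sched = bg_ions.setdefault(code, _Schedule(CODE_CAVITY))
            if seg.is_exotic:
                # pair in place for the full episode; transients just outside
                _walk_in(sched, code, seg.t_start - rank * p)
                if seg.t_end < duration:
                    _walk_out(sched, code, seg.t_end + rank * p)
            else:
                arrive = 0.0 if seg.t_start == 0 else seg.t_start + (6 + n - 1 - rank) * p
                _walk_in(sched, code, arrive)
                if seg.t_end < duration:
                    # finish a full phase before any exotic walk-in begins so
                    # the same atom never has two placements at one instant
                    _walk_out(sched, code, seg.t_end - (7 - rank) * p)
        for code in w_sites:
            sched = bg_waters.setdefault(code, _Schedule(_PARKED))
            sched.add(seg.t_start, code)
            sched.add(seg.t_end, _PARKED)

    # resting ions step down into the cavity around every event window
    for ev in timeline.events:
        seg = timeline.segment_at(ev.t_exit)
        k_sites = sorted(i + 1 for i, c in enumerate(seg.pattern) if c == K)
        n = len(k_sites)
        t = ev.t_exit
        for rank, code in enumerate(k_sites):
            sched = bg_ions[code]
            _walk_out(sched, code, t - (8 - rank) * p)
            _walk_in(sched, code, t + (4 + n - 1 - rank) * p)


_RESIDUE_NAMES = {74: "THR", 75: "THR", 76: "VAL", 77: "GLY", 78: "TYR", 79: "GLY", 80: "ASP"}
_CHAIN_IDS = ("A", "B", "C", "D")
_PHI_RESIDS = (75, 76, 77, 78, 79)
_PHI_FIXED_80 = -60.0


def render_frames(
    timeline: OccupancyTimeline,
    geom: SFGeometry | None = None,
    spec: BackboneSpec | None = None,
    frame_interval: float | None = None,
    seed: int = 0,
    jitter_sigma: float = 0.05,
) -> Trajectory:
    """Render a timeline into a coordinate-level :class:`Trajectory`.

    One frame per ``frame_interval`` (ns; defaults to the preset's value),
    covering t = 0 .. duration inclusive.  Each placed particle sits at its
    site's axial midpoint plus isotropic Gaussian jitter (``jitter_sigma``
    nm, truncated so the site assignment is preserved).  Four subunit
    backbones are rebuilt every frame with phi torsions drawn independently
    per frame, residue and chain from the preset distributions; rigid
    placement of each chain leaves all torsions intact.
    """
    geom = geom or default_geometry()
    spec = spec or BackboneSpec()
    params = timeline.params
    if frame_interval is None:
        frame_interval = params.frame_interval_ns
    if frame_interval <= 0 or frame_interval > timeline.duration:
        raise ValueError("frame_interval must be in (0, duration]")
    if jitter_sigma >= float(np.min(geom.site_width)) / 2.0:
        raise ValueError(
            "jitter sigma must be smaller than half the narrowest site height"
        )

    ss = np.random.SeedSequence(seed, spawn_key=(2,))
    rng_jitter, rng_phi = (np.random.default_rng(s) for s in ss.spawn(2))

    n_frames = int(math.floor(timeline.duration / frame_interval + 1e-9)) + 1
    times = np.arange(n_frames) * frame_interval

    # --- particle schedules ------------------------------------------------
    ion_pool = _Pool(CODE_CAVITY)
    water_pool = _Pool(_PARKED)
    for ev in sorted(timeline.events, key=lambda e: e.t_exit):
        _event_choreography(ev, ion_pool, water_pool)
    # ensure at least the canonical two transit slots exist
    while len(ion_pool.slots) < 2:
        ion_pool.slots.append(_Schedule(CODE_CAVITY))
    while len(water_pool.slots) < 2:
        water_pool.slots.append(_Schedule(_PARKED))

    bg_ions: dict[int, _Schedule] = {}
    bg_waters: dict[int, _Schedule] = {}
    _background_walkers(timeline, bg_ions, bg_waters)

    ion_schedules = ion_pool.slots + [bg_ions[k] for k in sorted(bg_ions)]
    water_schedules = water_pool.slots + [bg_waters[k] for k in sorted(bg_waters)]

    # --- particle coordinates ---------------------------------------------
    mids = geom.site_midpoints()
    z_lo = geom.z_array[:-1]
    z_hi = geom.z_array[1:]
    span = geom.plane_z[5] - geom.plane_z[0]
    z_special = {
        CODE_CAVITY: geom.plane_z[0] - 0.3 * span,
        CODE_EXTRACELLULAR: geom.plane_z[5] + 0.25 * span,
        _PARKED: geom.plane_z[0] - 0.55 * span,
    }
    eps = 1e-4

    n_particles = len(ion_schedules) + len(water_schedules)
    n_backbone = len(_CHAIN_IDS) * len(_RESIDUE_NAMES) * 4
    coords = np.empty((n_frames, n_particles + n_backbone, 3))

    def particle_coords(schedules: list[_Schedule], out: np.ndarray) -> None:
        for j, sched in enumerate(schedules):
            codes = sched.codes_at(times)
            base = np.empty(n_frames)
            lo = np.empty(n_frames)
            hi = np.empty(n_frames)
            in_site = (codes >= 1) & (codes <= 5)
            idx = codes[in_site] - 1
            base[in_site] = mids[idx]
            lo[in_site] = z_lo[idx] + eps
            hi[in_site] = z_hi[idx] - eps
            for code, zc in z_special.items():
                m = codes == code
                base[m] = zc
                if code == CODE_EXTRACELLULAR:
                    lo[m], hi[m] = geom.plane_z[5] + eps, zc + 10.0
                else:
                    lo[m], hi[m] = zc - 10.0, geom.plane_z[0] - eps
            xy = rng_jitter.normal(0.0, jitter_sigma, size=(n_frames, 2))
            z = np.clip(rng_jitter.normal(base, jitter_sigma), lo, hi)
            out[:, j, 0] = xy[:, 0]
            out[:, j, 1] = xy[:, 1]
            out[:, j, 2] = z

    n_ions = len(ion_schedules)
    particle_coords(ion_schedules, coords[:, :n_ions])
    particle_coords(water_schedules, coords[:, n_ions:n_particles])

    # --- backbones ---------------------------------------------------------
    resids = sorted(_RESIDUE_NAMES)
    n_res = len(resids)
    for ci, chain_id in enumerate(_CHAIN_IDS):
        phi = np.zeros((n_frames, n_res))
        for ri, resid in enumerate(resids):
            if resid in _PHI_RESIDS:
                key = f"{_RESIDUE_NAMES[resid]}{resid}"
                phi[:, ri] = params.phi[key].sample(rng_phi, n_frames)
            elif resid == 80:
                phi[:, ri] = _PHI_FIXED_80
        block = build_chain(phi, spec)  # (n_frames, n_res, 4, 3)
        ang = math.radians(90.0 * ci)
        rot = np.array(
            [
                [math.cos(ang), -math.sin(ang), 0.0],
                [math.sin(ang), math.cos(ang), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        shift = rot @ np.array([1.2, 0.35, geom.plane_z[0]])
        off = n_particles + ci * n_res * 4
        dest = coords[:, off : off + n_res * 4]
        np.matmul(block, rot.T, out=block)
        block += shift
        dest[:] = block.reshape(n_frames, n_res * 4, 3)

    # --- topology ----------------------------------------------------------
    rows: list[dict] = []
    for j in range(len(ion_schedules)):
        rows.append(
            dict(name="K", element="K", role=ROLE_ION, resname="K", resid=j + 1, chain="I")
        )
    for j in range(len(water_schedules)):
        rows.append(
            dict(name="O", element="O", role=ROLE_WATER, resname="HOH", resid=j + 1, chain="W")
        )
    atom_names = ("N", "CA", "C", "O")
    elements = ("N", "C", "C", "O")
    for chain_id in _CHAIN_IDS:
        for resid in resids:
            for name, el in zip(atom_names, elements):
                rows.append(
                    dict(
                        name=name,
                        element=el,
                        role=ROLE_BACKBONE,
                        resname=_RESIDUE_NAMES[resid],
                        resid=resid,
                        chain=chain_id,
                    )
                )
    topology = make_topology(rows)

    metadata = {
        "preset": params.name,
        "field": None if params.field is None else params.field.to_dict(),
        "timeline_seed": timeline.seed,
        "render_seed": seed,
        "frame_interval_ns": frame_interval,
        "n_ground_truth_events": len(timeline.events),
    }
    return Trajectory(times=times, coords=coords, topology=topology, metadata=metadata)
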