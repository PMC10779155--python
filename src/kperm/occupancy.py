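"""Frame-wise selectivity-filter occupancy analysis.

Classifies each frame's site contents (K+ ion, water oxygen, or empty, per
site S4..S0), measures the probability of the trapped "exotic" occupancy
states (K+ occupying exactly the (S4,S3) or (S3,S2) pair), classifies the
conduction mechanism of individual permeation events (direct vs soft
knock-on), and computes axial K+ density profiles with per-site integrated
occupancies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .permeation import PermeationEvent
from .sf_model import SFGeometry, site_codes
from .trajectory import ROLE_ION, ROLE_WATER, Trajectory

__all__ = [
    "OccupancyState",
    "StateProbabilityReport",
    "DensityProfile",
    "classify_frame",
    "exotic_fraction",
    "classify_mechanism",
    "density_profile",
]

EMPTY, W, K = "EMPTY", "W", "K"

_EXOTIC_S4S3 = frozenset({0, 1})  # site indices within S4..S0 ordering
_EXOTIC_S3S2 = frozenset({1, 2})


@dataclass(frozen=True)
class OccupancyState:
    """Per-site content of the SF in one frame, ordered S4..S0.

    ``multi_ion_sites`` flags sites holding more than one K+ (a geometric
    anomaly: a site cage fits a single dehydrated ion); it is reported, not
    fatal.  The exotic flags follow the strict definition -- K+ occupies
    exactly the named pair and no other SF site holds K+; ``permissive``
    relaxes this to "the pair is K-occupied", for sensitivity checks.
    """

    content: tuple[str, str, str, str, str]
    multi_ion_sites: tuple[int, ...] = ()
    permissive: bool = False

    @property
    def k_sites(self) -> frozenset[int]:
        return frozenset(i for i, c in enumerate(self.content) if c == K)

    @property
    def is_exotic_s4s3(self) -> bool:
        if self.permissive:
            return _EXOTIC_S4S3 <= self.k_sites
        return self.k_sites == _EXOTIC_S4S3

    @property
    def is_exotic_s3s2(self) -> bool:
        if self.permissive:
            return _EXOTIC_S3S2 <= self.k_sites
        return self.k_sites == _EXOTIC_S3S2

    @property
    def is_exotic(self) -> bool:
        # strict flags are mutually exclusive; permissive ones may overlap
        return self.is_exotic_s4s3 or self.is_exotic_s3s2

    @property
    def n_ions(self) -> int:
        return len(self.k_sites)

    def pattern(self) -> str:
        return ",".join(self.content)


@dataclass(frozen=True)
class StateProbabilityReport:
    """Frame-state census at a fixed sampling interval."""

    interval: float  # ns
    n_frames: int
    fractions: dict  # pattern string -> frame fraction
    exotic_fraction: float
    exotic_s4s3_fraction: float
    exotic_s3s2_fraction: float


@dataclass(frozen=True)
class DensityProfile:
    """Axial K+ density inside the SF, averaged over frames.

    Bin edges subdivide each site exactly, so per-site integrals partition
    the total: their sum equals the mean number of SF-resident ions per
    frame.
    """

    edges: np.ndarray  # nm
    density: np.ndarray  # ions / nm, one value per bin
    site_occupancy: dict  # site label -> mean ions in that site per frame
    mean_sf_ions: float


def _site_contents(
    traj: Trajectory, geom: SFGeometry, frame_indices: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Ion/water site census for the requested frames.

    Returns (ion_counts, water_counts), each (n_sel, 5) arrays of per-site
    particle counts ordered S4..S0.
    """
    frame_indices = np.asarray(frame_indices)
    ion_idx = traj.atoms_with_role(ROLE_ION)
    wat_idx = traj.atoms_with_role(ROLE_WATER)

    def census(atom_idx: np.ndarray) -> np.ndarray:
        counts = np.zeros((frame_indices.size, 5), dtype=int)
        if atom_idx.size == 0:
            return counts
        z = traj.coords[np.ix_(frame_indices, atom_idx)][:, :, 2]
        codes = site_codes(z, geom)  # (n_sel, n_atoms); 1..5 are SF sites
        for s in range(1, 6):
            counts[:, s - 1] = (codes == s).sum(axis=1)
        return counts

    return census(ion_idx), census(wat_idx)


def classify_frame(
    traj: Trajectory,
    frame_index: int,
    geom: SFGeometry,
    permissive: bool = False,
) -> OccupancyState:
    """Classify one frame's SF occupancy.

    A site is K if at least one ion maps to it (multiple ions are flagged as
    an anomaly), else W if at least one water oxygen maps there, else EMPTY.
    The result depends only on particle positions and roles, never on atom
    ordering.
    """
    ions, waters = _site_contents(traj, geom, np.array([frame_index]))
    ions, waters = ions[0], waters[0]
    content = tuple(
        K if ions[s] > 0 else (W if waters[s] > 0 else EMPTY) for s in range(5)
    )
    multi = tuple(int(s) for s in np.flatnonzero(ions > 1))
    return OccupancyState(content=content, multi_ion_sites=multi, permissive=permissive)


def exotic_fraction(
    traj: Trajectory,
    geom: SFGeometry,
    interval: float = 5.0,
    permissive: bool = False,
) -> StateProbabilityReport:
    """Exotic-state probability by frame census every ``interval`` ns.

    Classifies the frames nearest t = t0, t0 + interval, t0 + 2*interval, ...
    and reports the fraction of census frames in either exotic state,
    together with the full state-pattern distribution (which sums to 1).
    """
    if interval <= 0:
        raise ValueError("sampling interval must be positive")
    if traj.duration < interval:
        raise ValueError("trajectory span is shorter than the sampling interval")
    targets = traj.times[0] + np.arange(0.0, traj.duration + 1e-9, interval)
    idx = np.clip(np.searchsorted(traj.times, targets), 0, traj.n_frames - 1)
    left = np.clip(idx - 1, 0, traj.n_frames - 1)
    nearer_left = np.abs(traj.times[left] - targets) < np.abs(traj.times[idx] - targets)
    idx = np.unique(np.where(nearer_left, left, idx))

    ions, waters = _site_contents(traj, geom, idx)
    n = idx.size
    fractions: dict[str, float] = {}
    n_s4s3 = n_s3s2 = n_exotic = 0
    for i in range(n):
        content = tuple(
            K if ions[i, s] > 0 else (W if waters[i, s] > 0 else EMPTY)
            for s in range(5)
        )
        state = OccupancyState(content=content, permissive=permissive)
        key = state.pattern()
        fractions[key] = fractions.get(key, 0.0) + 1.0 / n
        if state.is_exotic_s4s3:
            n_s4s3 += 1
        if state.is_exotic_s3s2:
            n_s3s2 += 1
        if state.is_exotic:
            n_exotic += 1
    return StateProbabilityReport(
        interval=interval,
        n_frames=n,
        fractions=fractions,
        exotic_fraction=n_exotic / n,
        exotic_s4s3_fraction=n_s4s3 / n,
        exotic_s3s2_fraction=n_s3s2 / n,
    )


def _has_kwk(content_row: np.ndarray) -> bool:
    """True if two K-occupied sites are separated only by water sites."""
    k_pos = np.flatnonzero(content_row == 2)
    for a, b in zip(k_pos[:-1], k_pos[1:]):
        if b - a >= 2 and np.all(content_row[a + 1 : b] == 1):
            return True
    return False


def classify_mechanism(
    event: PermeationEvent, traj: Trajectory, geom: SFGeometry
) -> str:
    """Classify a permeation event as direct, soft, or mixed knock-on.

    Over the event's frames: if no frame places a water between two SF K+
    ions the conduction is a direct (Coulomb) knock-on; if at least half of
    the multi-ion frames show K-W-K patterning it is a soft knock-on;
    anything else is mixed.  Events spanning fewer than two frames return
    "insufficient".
    """
    sel = np.flatnonzero((traj.times >= event.t_enter) & (traj.times <= event.t_exit))
    if sel.size < 2:
        return "insufficient"
    ions, waters = _site_contents(traj, geom, sel)
    # encode content: 0 empty, 1 water, 2 ion
    content = np.where(ions > 0, 2, np.where(waters > 0, 1, 0))
    kwk = np.array([_has_kwk(row) for row in content])
    if not kwk.any():
        return "direct"
    multi = (ions > 0).sum(axis=1) >= 2
    if multi.sum() > 0 and kwk[multi].mean() >= 0.5:
        return "soft"
    return "mixed"


def density_profile(
    traj: Trajectory, geom: SFGeometry, bin_width: float = 0.02
) -> DensityProfile:
    """Histogram of SF-resident K+ axial positions, normalised per frame.

    Each site is subdivided into equal bins of width as close to
    ``bin_width`` as divides the site evenly, so site boundaries are always
    bin edges and per-site integrals are exact partitions of the total.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if traj.n_frames < 1:
        raise ValueError("need at least one frame")

    z_planes = geom.z_array
    edges_parts = []
    for k in range(5):
        n_sub = max(1, int(round((z_planes[k + 1] - z_planes[k]) / bin_width)))
        edges_parts.append(np.linspace(z_planes[k], z_planes[k + 1], n_sub + 1)[:-1])
    edges = np.concatenate(edges_parts + [[z_planes[5]]])

    ion_idx = traj.atoms_with_role(ROLE_ION)
    z = traj.z(ion_idx).ravel()
    z_sf = z[(z >= z_planes[0]) & (z < z_planes[5])]
    counts, _ = np.histogram(z_sf, bins=edges)
    widths = np.diff(edges)
    density = counts / (traj.n_frames * widths)

    site_occ = {}
    per_bin_mass = counts / traj.n_frames
    cursor = 0
    for k, label in enumerate(geom.site_labels):
        n_sub = len(edges_parts[k])
        site_occ[str(label)] = float(per_bin_mass[cursor : cursor + n_sub].sum())
        cursor += n_sub
    return DensityProfile(
        edges=edges,
        density=density,
        site_occupancy=site_occ,
        mean_sf_ions=float(per_bin_mass.sum()),
    )
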