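"""In-memory trajectory container: tagged particles over time.

A :class:`Trajectory` holds a fixed atom table (the topology, a pandas
DataFrame) and a dense coordinate block (n_frames, n_atoms, 3) in nm with
strictly increasing frame times in ns.  Atoms carry a functional role --
K+ ion, water oxygen, or backbone atom -- which is what every analysis keys
on; names/residues/chains exist for structure-format round trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "Frame", "ROLE_ION", "ROLE_WATER", "ROLE_BACKBONE", "make_topology"]

ROLE_ION = "ION_K"
ROLE_WATER = "WATER_O"
ROLE_BACKBONE = "BACKBONE"

TOPOLOGY_COLUMNS = ("id", "name", "element", "role", "resname", "resid", "chain")

DEFAULT_BOX = (8.0, 8.0, 9.4)  # nm, matching the simulated membrane system


def make_topology(rows: list[dict]) -> pd.DataFrame:
    """Build a topology table from per-atom dicts, assigning ids 0..n-1."""
    df = pd.DataFrame(rows)
    df["id"] = np.arange(len(df))
    return df[list(TOPOLOGY_COLUMNS)]


@dataclass(frozen=True)
class Frame:
    """One time point: frame time (ns) and per-atom coordinates (nm)."""

    time: float
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("frame coordinates must be finite")


@dataclass
class Trajectory:
    times: np.ndarray  # (n_frames,) ns
    coords: np.ndarray  # (n_frames, n_atoms, 3) nm
    topology: pd.DataFrame
    box: tuple[float, float, float] = DEFAULT_BOX
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.times.shape[0] != self.coords.shape[0]:
            raise ValueError("times and coords disagree on the frame count")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("topology and coords disagree on the atom count")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times.shape[0])

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[1])

    @property
    def duration(self) -> float:
        """Time span of the frames (ns)."""
        return float(self.times[-1] - self.times[0]) if self.n_frames else 0.0

    def frame(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coordinates=self.coords[i])

    def atoms_with_role(self, role: str) -> np.ndarray:
        """Indices of atoms carrying the given role."""
        return np.flatnonzero((self.topology["role"] == role).to_numpy())

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        top = self.topology
        mask = (
            (top["chain"] == chain) & (top["resid"] == resid) & (top["name"] == name)
        ).to_numpy()
        hits = np.flatnonzero(mask)
        if hits.size == 0:
            raise KeyError(f"no atom {name!r} in residue {resid} of chain {chain!r}")
        return int(hits[0])

    def z(self, atom_indices: np.ndarray | None = None) -> np.ndarray:
        """Axial (z) coordinates, shape (n_frames, len(atom_indices))."""
        if atom_indices is None:
            return self.coords[:, :, 2]
        return self.coords[:, atom_indices, 2]
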