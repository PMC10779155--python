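"""Trajectory input/output.

Three routes:

* a native plain-text frame container (versioned schema, lossless round
  trip) so the full pipeline never needs binary MD libraries;
* reference structures as standard PDB (coordinates in angstrom at the
  format boundary; the package computes in nm throughout);
* an adapter for external MD output (PDB/GRO structure + XTC/DCD frames)
  via MDAnalysis, with configurable role selections.

All writers are deterministic: identical input produces byte-identical
output (the formats carry no timestamps).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .trajectory import (
    DEFAULT_BOX,
    ROLE_BACKBONE,
    ROLE_ION,
    ROLE_WATER,
    Trajectory,
    make_topology,
)

__all__ = [
    "SCHEMA",
    "write_frames",
    "read_frames",
    "write_reference_pdb",
    "read_reference_pdb",
    "RoleMap",
    "adapt_external",
]

SCHEMA = "kperm-frames/1"


class FrameParseError(ValueError):
    """Raised when the native container violates its schema; carries the
    offending line number."""

    def __init__(self, line_no: int, message: str):
        super().__init__(f"line {line_no}: {message}")
        self.line_no = line_no


def write_frames(traj: Trajectory, path: str | Path) -> None:
    """Write the native text container: header (schema, metadata, box,
    topology), then one ``FRAME <time>`` block of per-atom coordinates per
    frame.  Floats use shortest-exact representation, so the round trip is
    lossless."""
    path = Path(path)
    lines = [f"# {SCHEMA}"]
    lines.append("META " + json.dumps(traj.metadata, sort_keys=True))
    lines.append("BOX " + " ".join(repr(float(v)) for v in traj.box))
    lines.append(f"NATOMS {traj.n_atoms}")
    for row in traj.topology.itertuples(index=False):
        lines.append(
            "ATOM\t"
            + "\t".join(
                str(v)
                for v in (row.id, row.name, row.element, row.role, row.resname, row.resid, row.chain)
            )
        )
    for i in range(traj.n_frames):
        lines.append(f"FRAME {float(traj.times[i])!r}")
        for a in range(traj.n_atoms):
            x, y, z = (float(v) for v in traj.coords[i, a])
            lines.append(f"{x!r} {y!r} {z!r}")
    path.write_text("\n".join(lines) + "\n")


def read_frames(path: str | Path) -> Trajectory:
    """Read the native container; schema violations raise
    :class:`FrameParseError` with the offending line number."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or lines[0].strip() != f"# {SCHEMA}":
        raise FrameParseError(1, f"missing schema header '# {SCHEMA}'")

    meta: dict = {}
    box = DEFAULT_BOX
    n_atoms = None
    rows: list[dict] = []
    i = 1
    while i < len(lines) and not lines[i].startswith("FRAME"):
        line = lines[i]
        try:
            if line.startswith("META "):
                meta = json.loads(line[5:])
            elif line.startswith("BOX "):
                box = tuple(float(v) for v in line[4:].split())
            elif line.startswith("NATOMS "):
                n_atoms = int(line[7:])
            elif line.startswith("ATOM\t"):
                _, _id, name, element, role, resname, resid, chain = line.split("\t")
                rows.append(
                    dict(
                        name=name,
                        element=element,
                        role=role,
                        resname=resname,
                        resid=int(resid),
                        chain=chain,
                    )
                )
            elif line.strip():
                raise ValueError(f"unexpected header line {line!r}")
        except FrameParseError:
            raise
        except Exception as exc:
            raise FrameParseError(i + 1, str(exc)) from exc
        i += 1

    if n_atoms is None or n_atoms != len(rows):
        raise FrameParseError(i, "NATOMS missing or inconsistent with ATOM records")

    times: list[float] = []
    frames: list[np.ndarray] = []
    while i < len(lines):
        header = lines[i]
        if not header.startswith("FRAME "):
            raise FrameParseError(i + 1, f"expected FRAME record, got {header!r}")
        try:
            times.append(float(header[6:]))
        except ValueError as exc:
            raise FrameParseError(i + 1, str(exc)) from exc
        block = lines[i + 1 : i + 1 + n_atoms]
        if len(block) < n_atoms:
            raise FrameParseError(
                len(lines), f"truncated frame: expected {n_atoms} coordinate lines"
            )
        try:
            coords = np.array([[float(v) for v in ln.split()] for ln in block])
            if coords.shape != (n_atoms, 3):
                raise ValueError("each coordinate line needs exactly 3 values")
        except FrameParseError:
            raise
        except Exception as exc:
            raise FrameParseError(i + 2, str(exc)) from exc
        frames.append(coords)
        i += 1 + n_atoms

    if not frames:
        raise FrameParseError(len(lines), "file contains no frames")
    return Trajectory(
        times=np.array(times),
        coords=np.stack(frames),
        topology=make_topology(rows),
        box=box,
        metadata=meta,
    )


def write_reference_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write frame 0 as a standard PDB (coordinates in angstrom).

    Ions and waters become HETATM records; backbone atoms keep their chain
    ids (subunits A-D).  Round-trips through :func:`read_reference_pdb` to
    the format's 3-decimal angstrom precision.
    """
    if traj.n_frames < 1:
        raise ValueError("need at least one frame to write a reference PDB")
    top = traj.topology
    n = traj.n_atoms
    arr = bst.AtomArray(n)
    arr.coord = (traj.coords[0] * 10.0).astype(np.float32)  # nm -> angstrom
    arr.chain_id = top["chain"].to_numpy(dtype="U4")
    arr.res_id = top["resid"].to_numpy(dtype=int)
    arr.res_name = top["resname"].to_numpy(dtype="U5")
    arr.atom_name = top["name"].to_numpy(dtype="U6")
    arr.element = top["element"].to_numpy(dtype="U2")
    arr.hetero = (top["role"] != ROLE_BACKBONE).to_numpy()
    pdb = bpdb.PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def _infer_role(element: str, resname: str) -> str:
    if element.upper() == "K" or resname.upper() in ("K", "POT", "K+"):
        return ROLE_ION
    if resname.upper() in ("HOH", "SOL", "WAT", "TIP3"):
        return ROLE_WATER
    return ROLE_BACKBONE


def read_reference_pdb(path: str | Path) -> Trajectory:
    """Read a PDB file into a single-frame trajectory (nm, t = 0)."""
    pdb = bpdb.PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    rows = [
        dict(
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]),
            role=_infer_role(str(arr.element[i]), str(arr.res_name[i])),
            resname=str(arr.res_name[i]),
            resid=int(arr.res_id[i]),
            chain=str(arr.chain_id[i]),
        )
        for i in range(arr.array_length())
    ]
    coords = (arr.coord / 10.0)[None, :, :]  # angstrom -> nm
    return Trajectory(times=np.array([0.0]), coords=coords, topology=make_topology(rows))


@dataclass(frozen=True)
class RoleMap:
    """MDAnalysis selection strings assigning analysis roles to atoms."""

    ion_selection: str = "resname K POT K+ NA SOD and not name CL"
    water_selection: str = "resname HOH SOL WAT TIP3 and name O OW OH2"
    backbone_selection: str = "name N CA C O and not resname HOH SOL WAT TIP3 K POT"


def adapt_external(
    structure_path: str | Path,
    traj_path: str | Path | None = None,
    role_map: RoleMap | None = None,
    recenter: bool = False,
) -> Trajectory:
    """Adapt an external MD trajectory (PDB/GRO + XTC/DCD) for analysis.

    Roles are assigned by the ``role_map`` selections; an empty K+ ion
    selection is a configuration error.  With ``recenter`` the per-frame
    centre of geometry of the backbone selection is subtracted, so axial
    coordinates are measured relative to the filter.  Coordinates convert
    from angstrom to nm; frame times from ps to ns (falling back to the
    frame index in ns when the source stores no usable time axis).
    """
    import MDAnalysis as mda

    role_map = role_map or RoleMap()
    u = (
        mda.Universe(str(structure_path))
        if traj_path is None
        else mda.Universe(str(structure_path), str(traj_path))
    )
    ions = u.select_atoms(role_map.ion_selection)
    waters = u.select_atoms(role_map.water_selection)
    backbone = u.select_atoms(role_map.backbone_selection)
    if len(ions) == 0:
        raise ValueError(
            f"role map selects no K+ ions (selection {role_map.ion_selection!r})"
        )

    groups = [(ions, ROLE_ION), (waters, ROLE_WATER), (backbone, ROLE_BACKBONE)]
    rows = []
    for group, role in groups:
        for atom in group:
            rows.append(
                dict(
                    name=atom.name,
                    element=getattr(atom, "element", atom.name[:1]) or atom.name[:1],
                    role=role,
                    resname=atom.resname,
                    resid=int(atom.resid),
                    chain=str(getattr(atom, "chainID", "") or atom.segid or "X"),
                )
            )

    times = []
    frames = []
    for ts in u.trajectory:
        times.append(float(ts.time) / 1000.0)  # ps -> ns
        parts = [group.positions / 10.0 for group, _ in groups]  # angstrom -> nm
        coord = np.concatenate([p for p in parts if len(p)], axis=0)
        if recenter:
            coord = coord - backbone.positions.mean(axis=0) / 10.0
        frames.append(coord)
    times_arr = np.asarray(times)
    if times_arr.size > 1 and not np.all(np.diff(times_arr) > 0):
        times_arr = np.arange(len(frames), dtype=float)

    box = tuple(float(v) / 10.0 for v in u.dimensions[:3]) if u.dimensions is not None else DEFAULT_BOX
    return Trajectory(
        times=times_arr,
        coords=np.stack(frames),
        topology=make_topology(rows),
        box=box,
        metadata={"source": str(structure_path), "recentered": recenter},
    )
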