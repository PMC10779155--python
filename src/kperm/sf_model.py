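"""Domain model of the KcsA selectivity filter and the applied THz field.

The selectivity filter (SF) is the conserved T-V-G-Y-G segment of the channel.
Five K+ binding sites S4..S0 are cages between six stacked planes of carbonyl
oxygens; S4 is innermost (cavity side), S0 opens to the extracellular space.
Axial convention: the pore axis is +z and intracellular -> extracellular is
increasing z, so an outward-permeating ion moves from CAVITY through S4..S0 to
EXTRACELLULAR.

Units: nm for lengths, degrees for angles, THz / ps for the field oscillation.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "SiteLabel",
    "SFGeometry",
    "AppliedField",
    "default_geometry",
    "site_of",
    "site_codes",
    "field_vector",
    "CODE_CAVITY",
    "CODE_EXTRACELLULAR",
    "SITE_CODES",
    "CODE_TO_LABEL",
]


class SiteLabel(enum.Enum):
    """Axial compartment of a particle: one of the five SF sites or the bulk
    regions below (CAVITY) and above (EXTRACELLULAR) the filter."""

    S4 = "S4"
    S3 = "S3"
    S2 = "S2"
    S1 = "S1"
    S0 = "S0"
    CAVITY = "CAVITY"
    EXTRACELLULAR = "EXTRACELLULAR"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


# Integer codes used by the vectorised classifiers: 0 = CAVITY, 1..5 = S4..S0
# in ascending z, 6 = EXTRACELLULAR.
CODE_CAVITY = 0
CODE_EXTRACELLULAR = 6
SITE_CODES = (1, 2, 3, 4, 5)
CODE_TO_LABEL = {
    0: SiteLabel.CAVITY,
    1: SiteLabel.S4,
    2: SiteLabel.S3,
    3: SiteLabel.S2,
    4: SiteLabel.S1,
    5: SiteLabel.S0,
    6: SiteLabel.EXTRACELLULAR,
}

_DEFAULT_PLANE_RESIDUES = (
    "THR75-OG1",
    "THR75-C=O",
    "VAL76-C=O",
    "GLY77-C=O",
    "TYR78-C=O",
    "GLY79-C=O",
)


@dataclass(frozen=True)
class SFGeometry:
    """Axial geometry of the selectivity filter.

    ``plane_z`` lists the six oxygen-plane coordinates (nm), strictly
    ascending from intracellular to extracellular.  Site k of
    ``site_labels`` = (S4, S3, S2, S1, S0) is bounded below by plane k and
    above by plane k+1; each site is the cage formed by the carbonyl (or
    THR75 hydroxyl) oxygens of two neighbouring residue planes.
    """

    plane_z: tuple[float, ...]
    plane_residue: tuple[str, ...] = _DEFAULT_PLANE_RESIDUES
    site_labels: tuple[SiteLabel, ...] = (
        SiteLabel.S4,
        SiteLabel.S3,
        SiteLabel.S2,
        SiteLabel.S1,
        SiteLabel.S0,
    )
    pore_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        z = np.asarray(self.plane_z, dtype=float)
        if z.shape != (6,):
            raise ValueError("plane_z must contain exactly 6 plane positions")
        if not np.all(np.diff(z) > 0):
            raise ValueError("plane_z must be strictly increasing")
        if len(self.plane_residue) != 6:
            raise ValueError("plane_residue must label all 6 planes")
        if len(self.site_labels) != 5:
            raise ValueError("exactly 5 sites are bounded by 6 planes")
        object.__setattr__(self, "plane_z", tuple(float(v) for v in z))

    @property
    def z_array(self) -> np.ndarray:
        return np.asarray(self.plane_z, dtype=float)

    @property
    def site_width(self) -> np.ndarray:
        """Axial height of each site S4..S0 (nm)."""
        return np.diff(self.z_array)

    def site_midpoints(self) -> np.ndarray:
        """Axial midpoint of each site S4..S0 (nm)."""
        z = self.z_array
        return 0.5 * (z[:-1] + z[1:])

    def site_bounds(self, label: SiteLabel) -> tuple[float, float]:
        k = self.site_labels.index(label)
        return self.plane_z[k], self.plane_z[k + 1]

    # -- plain-dict / file serialization ------------------------------------
    def to_dict(self) -> dict:
        return {
            "plane_z": list(self.plane_z),
            "plane_residue": list(self.plane_residue),
            "pore_axis": list(self.pore_axis),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SFGeometry":
        return cls(
            plane_z=tuple(d["plane_z"]),
            plane_residue=tuple(d.get("plane_residue", _DEFAULT_PLANE_RESIDUES)),
            pore_axis=tuple(d.get("pore_axis", (0.0, 0.0, 1.0))),
        )

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "SFGeometry":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.from_dict(data)


@dataclass(frozen=True)
class AppliedField:
    """Single-frequency oscillating electric field applied to the channel.

    The field lies in the XOZ plane; ``theta`` is the angle (degrees) between
    the field direction and the pore (z) axis, so theta = 0 points along the
    ion flow and theta = 90 perpendicular to it.  ``amplitude`` is in V/nm and
    ``frequency`` in THz (cycles per ps).

    The charge-imbalance metadata (``delta_q``) is carried for provenance
    only; it drives no computation in this package.
    """

    amplitude: float
    frequency: float
    theta: float
    phase: float = 0.0
    delta_q: float | None = None

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("field amplitude must be >= 0")
        if not (0.0 <= self.theta <= 90.0):
            warnings.warn(
                f"theta={self.theta} deg is outside the studied 0..90 deg range",
                stacklevel=3,
            )

    def to_dict(self) -> dict:
        d = {
            "amplitude": self.amplitude,
            "frequency": self.frequency,
            "theta": self.theta,
            "phase": self.phase,
        }
        if self.delta_q is not None:
            d["delta_q"] = self.delta_q
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AppliedField":
        return cls(
            amplitude=float(d["amplitude"]),
            frequency=float(d["frequency"]),
            theta=float(d["theta"]),
            phase=float(d.get("phase", 0.0)),
            delta_q=d.get("delta_q"),
        )


def default_geometry() -> SFGeometry:
    """Idealised SF geometry: six oxygen planes spaced 0.31 nm apart.

    0.31 nm is a typical carbonyl-plane separation in K+ channel filters; the
    geometry is fully configurable so planes measured from a real structure
    (e.g. an open-state KcsA model) can be substituted.
    """
    return SFGeometry(plane_z=tuple(round(0.31 * k, 10) for k in range(6)))


def site_codes(z: np.ndarray | float, geom: SFGeometry) -> np.ndarray:
    """Vectorised axial classification: 0=CAVITY, 1..5=S4..S0, 6=EXTRACELLULAR.

    Sites are half-open intervals [plane_k, plane_k+1), closed below, so a
    coordinate exactly on a plane belongs to the site above it.
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("axial coordinates must be finite")
    return np.searchsorted(geom.z_array, z, side="right").astype(np.int8)


def site_of(z: float, geom: SFGeometry) -> SiteLabel:
    """Map an axial coordinate (nm) to its compartment label.

    Half-open convention: z in [plane_k, plane_{k+1}) -> site k; z below the
    bottom plane -> CAVITY; z at or above the top plane -> EXTRACELLULAR.
    """
    if not math.isfinite(z):
        raise ValueError(f"axial coordinate must be finite, got {z!r}")
    return CODE_TO_LABEL[int(site_codes(z, geom))]


def field_vector(fld: AppliedField, t: float | np.ndarray) -> np.ndarray:
    """Instantaneous field vector E(t) in V/nm at time t (ps).

    E(t) = A cos(2 pi f t + phase) * (sin theta, 0, cos theta): a plane-wave
    electric field of amplitude A confined to the XOZ plane, tilted theta
    degrees off the pore axis.  With f in THz and t in ps, f*t is in cycles.
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    th = math.radians(fld.theta)
    direction = np.array([math.sin(th), 0.0, math.cos(th)])
    envelope = fld.amplitude * np.cos(2.0 * np.pi * fld.frequency * t + fld.phase)
    return np.multiply.outer(envelope, direction) if t.ndim else envelope * direction
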