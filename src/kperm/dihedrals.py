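"""Backbone phi-dihedral series and circular statistics.

The phi torsion of residue i is the signed dihedral C(i-1)-N(i)-CA(i)-C(i)
(IUPAC convention, principal interval (-180, 180]).  Distribution width is
summarised by the circular variance 1 - R_bar, where R_bar is the mean
resultant length of the unit vectors of the angles: 0 variance means a
perfectly concentrated (conformationally stable) residue.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "DihedralSeries",
    "CircularSummary",
    "dihedral",
    "phi_series",
    "circular_summary",
]


@dataclass(frozen=True)
class DihedralSeries:
    """Per-frame phi angles (deg) of one residue on one chain."""

    residue: str
    chain: str
    times: np.ndarray  # ns
    angles: np.ndarray  # deg, in (-180, 180]

    def __post_init__(self) -> None:
        if np.any(self.angles <= -180.0) or np.any(self.angles > 180.0):
            raise ValueError("angles must lie in (-180, 180]")


@dataclass(frozen=True)
class CircularSummary:
    mean_deg: float
    resultant_length: float  # R_bar in [0, 1]
    variance: float  # 1 - R_bar
    bin_width: float  # deg
    hist_edges: np.ndarray  # deg
    hist: np.ndarray  # probabilities, sum to 1
    n: int


def dihedral(p1, p2, p3, p4) -> np.ndarray | float:
    """Signed torsion angle (deg) of four points, vectorised over leading axes.

    Uses the two-plane-normal atan2 construction; result in (-180, 180].
    Raises on degenerate geometry (coincident or collinear consecutive
    points, where the torsion is undefined).
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    scale = max(
        float(np.max(np.linalg.norm(b1, axis=-1))),
        float(np.max(b2n)),
        float(np.max(np.linalg.norm(b3, axis=-1))),
    )
    if np.any(b2n == 0) or np.any(n1n <= 1e-12 * scale**2) or np.any(n2n <= 1e-12 * scale**2):
        raise ValueError("degenerate geometry: collinear or coincident points")
    m = np.cross(n1, n2)
    y = np.einsum("...i,...i->...", m, b2 / b2n[..., None])
    x = np.einsum("...i,...i->...", n1, n2)
    ang = np.degrees(np.arctan2(y, x))
    ang = np.where(ang <= -180.0, ang + 360.0, ang)
    return float(ang) if ang.ndim == 0 else ang


_RES_RE = re.compile(r"^([A-Za-z]+)?(\d+)$")


def phi_series(traj: Trajectory, residue: str | int, chain: str) -> DihedralSeries:
    """Per-frame phi torsion of ``residue`` (e.g. ``"GLY77"`` or 77) on
    ``chain``.

    Atoms are located by residue number and atom name; a missing atom raises
    a lookup error naming it.
    """
    if isinstance(residue, int):
        resid, label = residue, str(residue)
    else:
        m = _RES_RE.match(residue.strip())
        if not m:
            raise ValueError(f"cannot parse residue specifier {residue!r}")
        resid, label = int(m.group(2)), residue.strip()

    idx = [
        traj.atom_index(chain, resid - 1, "C"),
        traj.atom_index(chain, resid, "N"),
        traj.atom_index(chain, resid, "CA"),
        traj.atom_index(chain, resid, "C"),
    ]
    p = traj.coords[:, idx, :]
    angles = dihedral(p[:, 0], p[:, 1], p[:, 2], p[:, 3])
    return DihedralSeries(
        residue=label, chain=chain, times=traj.times, angles=np.atleast_1d(angles)
    )


def circular_summary(
    series: DihedralSeries | np.ndarray, bin_width: float = 5.0
) -> CircularSummary:
    """Circular mean, mean resultant length, variance and histogram.

    R_bar is the modulus of the average unit vector of the angles; the
    circular mean is its argument; the histogram covers (-180, 180] with
    ``bin_width``-deg bins and is normalised to sum to 1.
    """
    angles = series.angles if isinstance(series, DihedralSeries) else np.asarray(series, float)
    if angles.size < 2:
        raise ValueError("need at least two angles to summarise")
    if bin_width <= 0 or bin_width > 360:
        raise ValueError("bin_width must lie in (0, 360] deg")
    rad = np.radians(angles)
    mean_vec = np.array([np.cos(rad).mean(), np.sin(rad).mean()])
    r_bar = float(np.hypot(*mean_vec))
    mean_deg = float(np.degrees(np.arctan2(mean_vec[1], mean_vec[0])))
    n_bins = max(1, int(round(360.0 / bin_width)))
    edges = np.linspace(-180.0, 180.0, n_bins + 1)
    counts, _ = np.histogram(angles, bins=edges)
    return CircularSummary(
        mean_deg=mean_deg,
        resultant_length=r_bar,
        variance=1.0 - r_bar,
        bin_width=360.0 / n_bins,
        hist_edges=edges,
        hist=counts / angles.size,
        n=int(angles.size),
    )
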