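"""Torsion-to-Cartesian peptide backbone construction.

Builds N/CA/C/O backbone coordinates for a short chain by sequential natural
extension of reference frames (NeRF): each atom is placed from the previous
three using its bond length, bond angle and torsion.  Only the phi torsion is
variable per frame; psi and omega are held fixed, which is all the downstream
dihedral analysis requires.

Internal coordinates are the standard peptide values; lengths are stored in
nm (package convention) but quoted in angstrom in comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BackboneSpec", "place_atom", "build_chain"]


@dataclass(frozen=True)
class BackboneSpec:
    """Ideal peptide internal coordinates (lengths nm, angles deg).

    Defaults: N-CA 1.458 A, CA-C 1.525 A, C-N 1.329 A, C=O 1.231 A;
    C-N-CA 121.7, N-CA-C 111.2, CA-C-N 116.2, CA-C-O 120.5 deg;
    omega fixed at 180 deg (trans peptide), psi fixed per chain.
    """

    bond_n_ca: float = 0.1458
    bond_ca_c: float = 0.1525
    bond_c_n: float = 0.1329
    bond_c_o: float = 0.1231
    angle_c_n_ca: float = 121.7
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_ca_c_o: float = 120.5
    psi: float = 135.0
    omega: float = 180.0

    def __post_init__(self) -> None:
        for name in ("bond_n_ca", "bond_ca_c", "bond_c_n", "bond_c_o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("angle_c_n_ca", "angle_n_ca_c", "angle_ca_c_n", "angle_ca_c_o"):
            if not (0 < getattr(self, name) < 180):
                raise ValueError(f"{name} must lie in (0, 180) deg")


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # leaner than np.cross for the (..., 3) hot path
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def _norm(a: np.ndarray) -> np.ndarray:
    return np.sqrt(np.einsum("...i,...i->...", a, a))[..., None]


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float,
    torsion_deg: np.ndarray | float,
) -> np.ndarray:
    """Place atom D from reference atoms A, B, C.

    |CD| = ``bond``, angle(B, C, D) = ``angle_deg`` and the signed torsion
    A-B-C-D equals ``torsion_deg`` under the IUPAC atan2 convention.  Inputs
    broadcast over leading axes, so whole per-frame stacks are placed at once.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    theta = np.radians(angle_deg)
    phi = np.radians(np.asarray(torsion_deg, float))

    b1 = b - a
    b2 = c - b
    bc = b2 / _norm(b2)
    n = _cross(b1, b2)
    n /= _norm(n)
    m = _cross(n, bc)

    sin_t = np.sin(theta)
    d_local = (
        -np.cos(theta) * bc
        + (sin_t * np.cos(phi))[..., None] * m
        + (sin_t * np.sin(phi))[..., None] * n
    )
    return c + bond * d_local


def build_chain(phi_deg: np.ndarray, spec: BackboneSpec | None = None) -> np.ndarray:
    """Build backbone coordinates for ``n_res`` residues over ``n_frames``.

    Parameters
    ----------
    phi_deg
        Array (n_frames, n_res) of phi torsions C(i-1)-N(i)-CA(i)-C(i) in
        degrees.  ``phi_deg[:, 0]`` is ignored (the first residue has no
        preceding carbonyl carbon).
    spec
        Internal-coordinate set; defaults to :class:`BackboneSpec`.

    Returns
    -------
    ndarray
        Coordinates (n_frames, n_res, 4, 3) in nm, atom order N, CA, C, O
        per residue.  The chain is built in a local frame; callers apply any
        rigid placement (rotation + translation leaves all torsions intact).
    """
    spec = spec or BackboneSpec()
    phi_deg = np.atleast_2d(np.asarray(phi_deg, float))
    n_frames, n_res = phi_deg.shape
    if n_res < 1:
        raise ValueError("need at least one residue")

    out = np.empty((n_frames, n_res, 4, 3))

    # Seed residue in a local frame: N at origin, CA along +x, C in the xy
    # plane at the ideal N-CA-C angle.
    n0 = np.zeros((n_frames, 3))
    ca0 = np.zeros((n_frames, 3))
    ca0[:, 0] = spec.bond_n_ca
    ang = np.radians(spec.angle_n_ca_c)
    c0 = ca0 + spec.bond_ca_c * np.stack(
        [
            -np.cos(ang) * np.ones(n_frames),
            np.sin(ang) * np.ones(n_frames),
            np.zeros(n_frames),
        ],
        axis=-1,
    )
    prev_n, prev_ca, prev_c = n0, ca0, c0
    out[:, 0, 0], out[:, 0, 1], out[:, 0, 2] = prev_n, prev_ca, prev_c
    out[:, 0, 3] = place_atom(
        prev_n, prev_ca, prev_c, spec.bond_c_o, spec.angle_ca_c_o, spec.psi + 180.0
    )

    for i in range(1, n_res):
        n_i = place_atom(
            prev_n, prev_ca, prev_c, spec.bond_c_n, spec.angle_ca_c_n, spec.psi
        )
        ca_i = place_atom(
            prev_ca, prev_c, n_i, spec.bond_n_ca, spec.angle_c_n_ca, spec.omega
        )
        c_i = place_atom(
            prev_c, n_i, ca_i, spec.bond_ca_c, spec.angle_n_ca_c, phi_deg[:, i]
        )
        o_i = place_atom(
            n_i, ca_i, c_i, spec.bond_c_o, spec.angle_ca_c_o, spec.psi + 180.0
        )
        out[:, i, 0], out[:, i, 1], out[:, i, 2], out[:, i, 3] = n_i, ca_i, c_i, o_i
        prev_n, prev_ca, prev_c = n_i, ca_i, c_i

    return out
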