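"""Low-level torsion geometry: measuring and constructing dihedral angles.

All angles at this API are in degrees, following the convention used
throughout protein crystallography; signed dihedrals use the IUPAC rule
(positive when, looking down the b->c bond, the far bond rotates clockwise).
"""

from __future__ import annotations

import numpy as np

__all__ = ["measure_dihedral", "place_atom", "wrap_degrees", "bond_angle"]

_DEGENERACY_TOL = 1e-10


def wrap_degrees(angle: float) -> float:
    """Map an angle in degrees to the interval (-180, 180]."""
    a = (float(angle) + 180.0) % 360.0 - 180.0
    if a <= -180.0:
        a = 180.0
    return a


def measure_dihedral(a, b, c, d) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180].

    Computed with the two-plane-normal arctangent formulation, which is
    numerically stable near 0 and 180 degrees.  Raises ``ValueError`` on
    degenerate geometry (collinear a,b,c or b,c,d, or coincident b,c).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    b1 = b - a
    b2 = c - b
    b3 = d - c
    nb2 = np.linalg.norm(b2)
    if nb2 < _DEGENERACY_TOL:
        raise ValueError("degenerate dihedral: points b and c coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < _DEGENERACY_TOL:
        raise ValueError("degenerate dihedral: a, b, c are collinear")
    if np.linalg.norm(n2) < _DEGENERACY_TOL:
        raise ValueError("degenerate dihedral: b, c, d are collinear")
    u = b2 / nb2
    y = float(np.dot(np.cross(n1, n2), u))
    x = float(np.dot(n1, n2))
    return wrap_degrees(np.degrees(np.arctan2(y, x)))


def bond_angle(a, b, c) -> float:
    """Angle a-b-c in degrees, in [0, 180]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    v1 = a - b
    v2 = c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def place_atom(a, b, c, length: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a, b, c.

    D is bonded to ``c`` at distance ``length`` (angstrom), with bond angle
    b-c-D of ``angle`` degrees and dihedral a-b-c-D of ``torsion`` degrees,
    such that ``measure_dihedral(a, b, c, D) == torsion``.

    This is the standard natural-extension (NeRF) construction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    ang = np.radians(angle)
    tor = np.radians(torsion)

    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < _DEGENERACY_TOL:
        raise ValueError("degenerate reference frame: a, b, c are collinear")
    n /= nn
    m = np.cross(n, bc)

    d_local = np.array(
        [
            -length * np.cos(ang),
            length * np.sin(ang) * np.cos(tor),
            length * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n
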