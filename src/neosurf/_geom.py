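"""Small geometry helpers shared by the builders: internal-coordinate atom
placement (NeRF), dihedral measurement and axis rotations."""

from __future__ import annotations

import numpy as np


def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, IUPAC sign convention."""
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    return float(np.degrees(np.arctan2(y, x)))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, dih: float) -> np.ndarray:
    """Place atom D given positions of A, B, C and the internal coordinates
    |C-D| = bond, angle(B,C,D) = angle (deg), dihedral(A,B,C,D) = dih (deg).

    Natural extension reference frame construction.
    """
    ang = np.radians(angle)
    tor = np.radians(dih)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * np.cos(ang),
                   bond * np.sin(ang) * np.cos(tor),
                   bond * np.sin(ang) * np.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about a (unit) axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    ct, st = np.cos(t), np.sin(t)
    x, y, z = axis
    K = np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])
    return ct * np.eye(3) + st * K + (1.0 - ct) * np.outer(axis, axis)


def rotate_about_bond(coords: np.ndarray, origin: np.ndarray,
                      axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a set of coordinates about the line through *origin* along *axis*."""
    R = rotation_about_axis(axis, angle_deg)
    return (coords - origin) @ R.T + origin
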