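"""Small rigid-body geometry toolkit shared by all analysis modules.

Everything operates on plain numpy arrays: points are shape ``(3,)`` or
``(n, 3)``, rotations are ``(3, 3)`` proper orthonormal matrices whose
*columns* are the frame axes.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "unit",
    "angle_between",
    "signed_angle",
    "dihedral",
    "rotation_about_axis",
    "rotation_angle",
    "rotation_axis",
    "kabsch",
    "place_atom",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` scaled to unit length."""
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("cannot normalize zero vector")
    return v / n


def angle_between(a: np.ndarray, b: np.ndarray) -> float:
    """Unsigned angle between two vectors, degrees, in [0, 180]."""
    c = np.dot(unit(a), unit(b))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def signed_angle(a: np.ndarray, b: np.ndarray, axis: np.ndarray) -> float:
    """Signed angle (degrees) from ``a`` to ``b`` about ``axis`` (right-handed)."""
    axis = unit(axis)
    a = a - np.dot(a, axis) * axis
    b = b - np.dot(b, axis) * axis
    ang = np.degrees(np.arctan2(np.dot(np.cross(a, b), axis), np.dot(a, b)))
    return float(ang)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Torsion angle p0-p1-p2-p3 in degrees, IUPAC sign convention, (-180, 180]."""
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, unit(b1))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    ang = float(np.degrees(np.arctan2(y, x)))
    return 180.0 if ang <= -180.0 else ang


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    a = unit(np.asarray(axis, dtype=float))
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(a, a)


def rotation_angle(R: np.ndarray) -> float:
    """Rotation angle of a rotation matrix, degrees, in [0, 180]."""
    c = (np.trace(R) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_axis(R: np.ndarray) -> np.ndarray:
    """Unit rotation axis of ``R`` (undefined sign for 180 deg rotations)."""
    w, v = np.linalg.eig(R)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    axis = unit(axis)
    # orient so that the rotation is right-handed positive about the axis
    t = np.array([0.0, 0.0, 0.0])
    t[int(np.argmin(np.abs(axis)))] = 1.0
    p = np.cross(axis, t)
    if np.dot(np.cross(p, R @ p), axis) < 0:
        axis = -axis
    return axis


def kabsch(template: np.ndarray, observed: np.ndarray):
    """Least-squares rigid superposition ``observed ~ R @ template + t``.

    Returns ``(R, t, rmsd)`` with ``R`` proper (det = +1).
    """
    P = np.asarray(template, dtype=float)
    Q = np.asarray(observed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((Q - (P @ R.T + t)) ** 2, axis=1))))
    return R, t, rmsd


def place_atom(
    p0: np.ndarray,
    p1: np.ndarray,
    p2: np.ndarray,
    bond: float,
    angle_deg: float,
    dihedral_deg: float,
) -> np.ndarray:
    """NeRF atom placement: new atom D bonded to ``p2`` with B-C-D angle and
    A-B-C-D torsion given by ``angle_deg`` / ``dihedral_deg`` (A=p0, B=p1, C=p2)."""
    t = np.radians(np.array([angle_deg, dihedral_deg]))
    bc = unit(p2 - p1)
    n = unit(np.cross(p1 - p0, bc))
    m = np.cross(n, bc)
    d = bond * np.array(
        [
            -np.cos(t[0]),
            np.sin(t[0]) * np.cos(t[1]),
            np.sin(t[0]) * np.sin(t[1]),
        ]
    )
    return p2 + d[0] * bc + d[1] * m + d[2] * n
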