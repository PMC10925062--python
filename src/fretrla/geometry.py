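"""Low-level rigid-body and torsion geometry shared across the package.

Conventions
-----------
* Coordinates are in ångström.
* Torsion angles are in degrees on the half-open interval (-180, 180],
  with the IUPAC sign convention (cis = 0, trans = 180).
* Rotations are proper (determinant +1); reflections are never produced.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "wrap_deg",
    "dihedrals",
    "circular_mean",
    "kabsch",
    "attachment_frame",
    "to_local",
    "nerf_place",
]


class DegenerateGeometryError(ValueError):
    """A torsion is undefined because three consecutive atoms are collinear."""


def wrap_deg(angles: np.ndarray | float) -> np.ndarray:
    """Wrap angles in degrees into the interval (-180, 180]."""
    a = np.mod(np.asarray(angles, dtype=float) + 180.0, 360.0) - 180.0
    return np.where(a == -180.0, 180.0, a)


def dihedrals(p0, p1, p2, p3):
    """Signed torsion angle (degrees) for four points; broadcasts over leading axes.

    Uses the atan2 formulation, which is numerically stable near 0 and 180:
    with b1 = p1-p0, b2 = p2-p1, b3 = p3-p2,
    x = (b1 x b2).(b2 x b3) and y = ((b1 x b2) x b2_hat).(b2 x b3).

    Raises
    ------
    DegenerateGeometryError
        If three consecutive atoms are (near-)collinear anywhere in the batch.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    scale1 = np.linalg.norm(b1, axis=-1) * np.linalg.norm(b2, axis=-1)
    scale2 = np.linalg.norm(b2, axis=-1) * np.linalg.norm(b3, axis=-1)
    bad = (np.linalg.norm(n1, axis=-1) <= 1e-8 * scale1) | (
        np.linalg.norm(n2, axis=-1) <= 1e-8 * scale2
    )
    if np.any(bad):
        idx = np.argwhere(np.atleast_1d(bad))
        raise DegenerateGeometryError(
            f"collinear atoms make the torsion undefined at batch index {idx[0].tolist()}"
        )
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(n1, b2n)
    x = np.einsum("...i,...i->...", n1, n2)
    y = np.einsum("...i,...i->...", m, n2)
    return wrap_deg(np.degrees(np.arctan2(y, x)))


def circular_mean(angles_deg: np.ndarray, axis: int = -1):
    """Circular mean of angles in degrees.

    Returns
    -------
    mean : ndarray
        Mean direction in (-180, 180].
    resultant : ndarray
        Mean resultant length in [0, 1]; values near zero mean the mean
        direction is ill-defined (e.g. two antipodal angles).
    """
    a = np.radians(np.asarray(angles_deg, dtype=float))
    s = np.sin(a).mean(axis=axis)
    c = np.cos(a).mean(axis=axis)
    return wrap_deg(np.degrees(np.arctan2(s, c))), np.hypot(s, c)


def kabsch(P: np.ndarray, Q: np.ndarray):
    """Least-squares rigid superposition mapping point set P onto Q.

    Returns the proper rotation ``R`` and translation ``t`` minimizing
    ``||(P @ R.T + t) - Q||``; reflections are excluded by construction.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    return R, t


def attachment_frame(n: np.ndarray, ca: np.ndarray, c: np.ndarray):
    """Orthonormal attachment-local frame from a backbone triad (N, CA, C).

    Origin at CA; x along CA->N, z along (CA->N) x (CA->C), y completing the
    right-handed set. Returns ``(origin, B)`` with basis vectors as the
    columns of ``B``.
    """
    u = np.asarray(n, float) - ca
    v = np.asarray(c, float) - ca
    x = u / np.linalg.norm(u)
    z = np.cross(u, v)
    nz = np.linalg.norm(z)
    if nz < 1e-8:
        raise DegenerateGeometryError("backbone triad is collinear")
    z = z / nz
    y = np.cross(z, x)
    return np.asarray(ca, float), np.column_stack([x, y, z])


def to_local(coords: np.ndarray, origin: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Express coordinates in the local frame defined by ``origin``/``basis``."""
    return (np.asarray(coords, float) - origin) @ basis


def nerf_place(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place the next atom D of a chain A-B-C-D by internal coordinates.

    ``bond`` is |C-D|, ``angle_deg`` the B-C-D bond angle and ``torsion_deg``
    the A-B-C-D torsion, consistent in sign with :func:`dihedrals`.
    """
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)
    d2 = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            -bond * np.sin(theta) * np.sin(phi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    M = np.column_stack([bc, m, n])
    return c + M @ d2
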