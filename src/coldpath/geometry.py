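"""Low-level vector geometry: angles, dihedrals, internal-coordinate placement,
and rigid-body superposition.

All angular quantities are in degrees.  Every routine broadcasts over leading
axes so that a whole batch of frames can be processed in one call; the last
axis is always the spatial (x, y, z) axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "wrap_angle",
    "bond_length",
    "bond_angle",
    "dihedral",
    "nerf_place",
    "kabsch_rotation",
    "superpose",
]


def wrap_angle(a):
    """Wrap angle(s) in degrees into (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -np.mod(-a + 180.0, 360.0) + 180.0
    return wrapped


def bond_length(a, b):
    return np.linalg.norm(np.asarray(b) - np.asarray(a), axis=-1)


def bond_angle(a, b, c):
    """Angle a-b-c in degrees, vertex at b."""
    u = np.asarray(a) - np.asarray(b)
    v = np.asarray(c) - np.asarray(b)
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cosang = np.sum(u * v, axis=-1) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def dihedral(a, b, c, d):
    """Signed dihedral a-b-c-d in degrees, in (-180, 180].

    IUPAC convention: looking from b towards c, a clockwise rotation of the
    far bond (c-d) relative to the near bond (b-a) is positive.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    b1 = b - a
    b2 = c - b
    b3 = d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m = np.cross(n1, b2n)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(m * n2, axis=-1)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def is_collinear(a, b, c, tol: float = 1e-6) -> np.ndarray:
    """True where points a, b, c are (nearly) collinear."""
    u = np.asarray(b) - np.asarray(a)
    v = np.asarray(c) - np.asarray(b)
    cr = np.cross(u, v)
    return np.linalg.norm(cr, axis=-1) <= tol * (
        np.linalg.norm(u, axis=-1) * np.linalg.norm(v, axis=-1) + 1e-30
    )


def nerf_place(ref, g, p, r, theta, phi):
    """Place atom D from three placed atoms by internal coordinates (NeRF).

    Parameters
    ----------
    ref, g, p : positions of the dihedral reference atom A, the angle atom B
        and the bonded parent atom C (arrays broadcastable to (..., 3)).
    r : bond length C-D (scalar or (...,)).
    theta : bond angle B-C-D in degrees.
    phi : dihedral A-B-C-D in degrees.

    Returns the position of D such that ``dihedral(ref, g, p, D) == phi`` and
    ``bond_angle(g, p, D) == theta``.
    """
    ref, g, p = (np.asarray(x, dtype=float) for x in (ref, g, p))
    r = np.asarray(r, dtype=float)[..., None]
    th = np.radians(np.asarray(theta, dtype=float))[..., None]
    ph = np.radians(np.asarray(phi, dtype=float))[..., None]

    bc = p - g
    bc_hat = bc / np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = g - ref
    n = np.cross(ab, bc_hat)
    n_hat = n / np.linalg.norm(n, axis=-1, keepdims=True)
    m_hat = np.cross(n_hat, bc_hat)

    d_local_x = -r * np.cos(th)
    d_local_y = r * np.sin(th) * np.cos(ph)
    d_local_z = -r * np.sin(th) * np.sin(ph)
    return p + bc_hat * d_local_x + m_hat * d_local_y + n_hat * d_local_z


def kabsch_rotation(moving: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rotation matrix R (3x3) minimising |R @ moving.T - target.T|.

    Inputs must already be centred on their centroids.
    """
    h = moving.T @ target
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    return vt.T @ corr @ u.T


def superpose(
    coords: np.ndarray,
    target: np.ndarray,
    fit_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares rigid superposition of ``coords`` onto ``target``.

    The transform is fitted on ``fit_mask`` atoms (all atoms if None) and
    applied to every atom.  Accepts a single frame (n, 3) or a batch
    (m, n, 3); frames are superposed independently.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        return _superpose_one(coords, target, fit_mask)
    return np.stack([_superpose_one(f, target, fit_mask) for f in coords])


def _superpose_one(coords, target, fit_mask):
    sel = slice(None) if fit_mask is None else fit_mask
    mob = coords[sel]
    tgt = target[sel]
    mob_c = mob.mean(axis=0)
    tgt_c = tgt.mean(axis=0)
    rot = kabsch_rotation(mob - mob_c, tgt - tgt_c)
    return (coords - mob_c) @ rot.T + tgt_c


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain (non-superposing) root-mean-square deviation between point sets."""
    d = np.asarray(a) - np.asarray(b)
    return float(np.sqrt(np.mean(np.sum(d * d, axis=-1))))
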