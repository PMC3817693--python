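"""Vector geometry primitives: dihedrals, bond angles, internal-coordinate
atom placement (NeRF), axis rotations, rigid superposition, and the derived
amide-H / virtual-CB constructions with their analytic Jacobians.

All public angle arguments and returns are in degrees; coordinates in A.
Functions accept arrays with leading batch axes where noted.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from . import constants as k

_EPS = 1e-12


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180].

    Uses the praxeolitic formulation; broadcasts over leading axes.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> 180 so results live in (-180, 180]
    return np.where(ang <= -180.0, ang + 360.0, ang)


def bond_angle(a, b, c) -> np.ndarray:
    """Bond angle a-b-c at vertex b, degrees in [0, 180]."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = _unit(a - b)
    v = _unit(c - b)
    cos = np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def place_atom(a, b, c, bond: float, angle_deg, torsion_deg) -> np.ndarray:
    """Place atom d with |c-d| = bond, angle(b,c,d) = angle_deg and
    dihedral(a,b,c,d) = torsion_deg (NeRF construction). Broadcasts."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = np.stack(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    return c + (
        d_local[..., :1] * bc + d_local[..., 1:2] * m + d_local[..., 2:3] * n
    )


def rotate_about_axis(points: np.ndarray, origin, axis, angle_deg: float) -> np.ndarray:
    """Rotate points about the line through `origin` with direction `axis`."""
    rot = Rotation.from_rotvec(np.radians(angle_deg) * _unit(np.asarray(axis, float)))
    return rot.apply(np.asarray(points, float) - origin) + origin


def kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (R, t, rmsd) with x' = x @ R.T + t.
    """
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, rssd = Rotation.align_vectors(target - tc, mobile - mc)
    rmsd = rssd / np.sqrt(len(mobile))
    r_mat = rot.as_matrix()
    t = tc - mc @ r_mat.T
    return r_mat, t, float(rmsd)


# ---------------------------------------------------------------------------
# Derivatives of angles/dihedrals with respect to Cartesian coordinates.
# Gradients are returned in radians per A.
# ---------------------------------------------------------------------------

def dihedral_grad(p0, p1, p2, p3):
    """d(dihedral)/d(p0..p3) in rad/A, batched over leading axes.

    Returns four arrays of shape like the inputs.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1, keepdims=True)
    n1sq = np.sum(n1 * n1, axis=-1, keepdims=True)
    n2sq = np.sum(n2 * n2, axis=-1, keepdims=True)
    g0 = -b2n / np.maximum(n1sq, _EPS) * n1
    g3 = b2n / np.maximum(n2sq, _EPS) * n2
    d12 = np.sum(b1 * b2, axis=-1, keepdims=True) / np.maximum(b2n**2, _EPS)
    d32 = np.sum(b3 * b2, axis=-1, keepdims=True) / np.maximum(b2n**2, _EPS)
    g1 = -(1.0 + d12) * g0 + d32 * g3
    g2 = d12 * g0 - (1.0 + d32) * g3
    return g0, g1, g2, g3


def bond_angle_grad(a, b, c):
    """d(angle at b)/d(a,b,c) in rad/A, batched."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    u = a - b
    v = c - b
    nu = np.linalg.norm(u, axis=-1, keepdims=True)
    nv = np.linalg.norm(v, axis=-1, keepdims=True)
    uh = u / nu
    vh = v / nv
    cos = np.clip(np.sum(uh * vh, axis=-1, keepdims=True), -1.0, 1.0)
    sin = np.sqrt(np.maximum(1.0 - cos**2, _EPS))
    ga = (cos * uh - vh) / (nu * sin)
    gc = (cos * vh - uh) / (nv * sin)
    gb = -ga - gc
    return ga, gb, gc


# ---------------------------------------------------------------------------
# Derived interaction centres.
#
# Virtual CB: the standard linear/cross-product tetrahedral construction
#   b = CA - N, c = C - CA, a = b x c
#   CB = CA - 0.58273431 a + 0.56802827 b - 0.54067466 c
# which is polynomial in the backbone coordinates, so its Jacobians are exact
# closed forms (no normalisation involved).
#
# Amide H: placed 1.01 A from N along the (outward) bisector of the two bond
# vectors, h = N + L * unit(2N - CA - C_prev).
# ---------------------------------------------------------------------------

_CB_A = -0.58273431
_CB_B = 0.56802827
_CB_C = -0.54067466


def _skew(v: np.ndarray) -> np.ndarray:
    """Batched skew matrix S with S @ x = v x x. v: (..., 3) -> (..., 3, 3)."""
    v = np.asarray(v, float)
    out = np.zeros(v.shape + (3,), dtype=float)
    out[..., 0, 1] = -v[..., 2]
    out[..., 0, 2] = v[..., 1]
    out[..., 1, 0] = v[..., 2]
    out[..., 1, 2] = -v[..., 0]
    out[..., 2, 0] = -v[..., 1]
    out[..., 2, 1] = v[..., 0]
    return out


def virtual_cb(n, ca, c):
    """Virtual CB position from backbone N, CA, C (batched)."""
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    return ca + _CB_A * a + _CB_B * b + _CB_C * cv


def virtual_cb_jacobians(n, ca, c):
    """Jacobians d(CB)/d(N, CA, C), each (..., 3, 3)."""
    n, ca, c = (np.asarray(p, dtype=float) for p in (n, ca, c))
    b = ca - n
    cv = c - ca
    eye = np.broadcast_to(np.eye(3), b.shape + (3,))
    # a = b x c; da/db = -skew(c), da/dc = skew(b)
    da_db = -_skew(cv)
    da_dc = _skew(b)
    # d(cb)/dn: db/dn = -I, dc/dn = 0
    j_n = _CB_A * (da_db @ (-np.eye(3))) + _CB_B * (-eye)
    # d(cb)/dca: I + A*(da/db*I + da/dc*(-I)) + B*I + C*(-I)
    j_ca = eye + _CB_A * (da_db - da_dc) + (_CB_B - _CB_C) * eye
    # d(cb)/dc: A*da_dc + C*I
    j_c = _CB_A * da_dc + _CB_C * eye
    return j_n, j_ca, j_c


def amide_h(n, ca, c_prev):
    """Amide hydrogen position on N (batched)."""
    n, ca, c_prev = (np.asarray(p, dtype=float) for p in (n, ca, c_prev))
    u = 2.0 * n - ca - c_prev
    return n + k.BOND_N_H * _unit(u)


def amide_h_jacobians(n, ca, c_prev):
    """Jacobians d(H)/d(N, CA, C_prev), each (..., 3, 3)."""
    n, ca, c_prev = (np.asarray(p, dtype=float) for p in (n, ca, c_prev))
    u = 2.0 * n - ca - c_prev
    nu = np.linalg.norm(u, axis=-1, keepdims=True)
    uh = u / nu
    eye = np.broadcast_to(np.eye(3), u.shape + (3,))
    proj = (eye - uh[..., :, None] * uh[..., None, :]) / nu[..., None]
    j_n = eye + k.BOND_N_H * 2.0 * proj
    j_ca = -k.BOND_N_H * proj
    j_cp = -k.BOND_N_H * proj
    return j_n, j_ca, j_cp


def wrap_angle(a):
    """Wrap angle(s) in degrees to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    out = (a + 180.0) % 360.0 - 180.0
    return np.where(out <= -180.0, out + 360.0, out)
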