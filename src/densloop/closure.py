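"""Geometric chain closure by cyclic coordinate descent (CCD).

A broken chain is closed against three anchor atoms: the N, CA, C of the
residue just past the cutpoint, whose coordinates are fixed by the template
side.  A "moving" copy of those three atoms is carried at the end of the
N-side piece (built by ideal-geometry extension across the cutpoint); each
CCD step rotates one movable phi/psi torsion by the closed-form angle that
minimises the summed squared anchor deviation, so the deviation is
non-increasing by construction.  Omega torsions are held trans.

This is deliberately a *purely geometric* closure: no Ramachandran or
clash filtering happens inside the loop, which reproduces the tendency of
geometric closure to leave strained backbone geometry (that strain is the
motivation for the minimization-based alternative in
:mod:`densloop.minimize`).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import constants as k
from . import geometry as geom
from .model import BackboneModel, N, CA, C, O


@dataclasses.dataclass
class CCDReport:
    closed: bool
    final_dev: float  # RMS anchor deviation, A
    iterations: int
    dev_trace: list[float]


def _extension_anchors(model: BackboneModel, cut: int) -> np.ndarray:
    """Moving copies of N, CA, C of residue cut+1, built by ideal-geometry
    extension from residue ``cut`` using the stored torsions (omega trans)."""
    c = model.coords
    t = model.torsions
    psi = t[cut, 1] if np.isfinite(t[cut, 1]) else 180.0
    phi_next = t[cut + 1, 0] if np.isfinite(t[cut + 1, 0]) else -120.0
    n_x = geom.place_atom(c[cut, N], c[cut, CA], c[cut, C],
                          k.BOND_C_N, k.ANGLE_CA_C_N, psi)
    ca_x = geom.place_atom(c[cut, CA], c[cut, C], n_x,
                           k.BOND_N_CA, k.ANGLE_C_N_CA, k.OMEGA_IDEAL)
    c_x = geom.place_atom(c[cut, C], n_x, ca_x,
                          k.BOND_CA_C, k.ANGLE_N_CA_C, phi_next)
    return np.stack([n_x, ca_x, c_x])


def _optimal_rotation(moving: np.ndarray, fixed: np.ndarray,
                      origin: np.ndarray, axis: np.ndarray) -> float:
    """Closed-form CCD angle (degrees) about the given axis minimising
    sum_i |fixed_i - R(theta) moving_i|^2."""
    u = axis / np.linalg.norm(axis)
    a = 0.0
    b = 0.0
    for m_pt, f_pt in zip(moving, fixed):
        o = origin + np.dot(m_pt - origin, u) * u  # projection onto axis
        r = m_pt - o
        rn = np.linalg.norm(r)
        if rn < 1e-9:
            continue
        s = r / rn
        t_vec = np.cross(u, s)
        f = f_pt - o
        a += rn * np.dot(f, s)
        b += rn * np.dot(f, t_vec)
    if a == 0.0 and b == 0.0:
        return 0.0
    return float(np.degrees(np.arctan2(b, a)))


def ccd_close(model: BackboneModel, segment: tuple[int, int], cutpoint: int,
              max_iters: int = 100, tol: float = 0.08,
              step_cap: float = 60.0, alternate: bool = True):
    """Close the chain break at ``cutpoint`` by CCD over the movable phi/psi
    torsions of ``segment`` (model indices, closed interval).

    Returns ``(model, report)`` with the model modified in place: segment
    coordinates updated, torsions re-synchronised, and the cutpoint break
    flag cleared when the final RMS anchor deviation is within ``tol``.
    With ``alternate=True`` the sweep also adjusts torsions on the C side of
    the cutpoint (which move the anchor targets toward the N-side chain).
    """
    s, e = segment
    if not (s <= cutpoint < e):
        raise ValueError("cutpoint must lie inside the movable segment")
    if cutpoint + 1 >= model.n_res:
        raise ValueError("no anchor residue past the cutpoint")
    n_side = [(j, tor) for j in range(max(s, 1), cutpoint + 1) for tor in (0, 1)]
    c_side = [(j, tor) for j in range(cutpoint + 1, e + 1) for tor in (0, 1)] \
        if alternate else []
    if not n_side and not c_side:
        raise ValueError("segment has no movable torsions")

    coords = model.coords
    anchors_fixed = coords[cutpoint + 1, :3].copy()  # N, CA, C targets
    anchors_moving = _extension_anchors(model, cutpoint)

    def dev() -> float:
        return float(np.sqrt(np.mean(
            np.sum((anchors_moving - anchors_fixed) ** 2, axis=1))))

    trace = [dev()]
    if trace[0] <= tol:
        return model, CCDReport(True, trace[0], 0, trace)

    def moving_block_n(j: int, tor: int):
        """Atom coordinates (views stacked) moving with torsion tor of
        residue j on the N side, plus the extension anchors."""
        pts = [coords[j, C][None], coords[j, O][None]] if tor == 0 \
            else [coords[j, O][None]]
        if j + 1 <= cutpoint:
            pts.append(coords[j + 1:cutpoint + 1].reshape(-1, 3))
        pts.append(anchors_moving)
        return pts

    def moving_block_c(j: int, tor: int):
        pts = []
        if cutpoint + 1 <= j - 1:
            pts.append(coords[cutpoint + 1:j].reshape(-1, 3))
        if tor == 1:
            pts.append(coords[j, N][None])
        return pts

    it = 0
    for it in range(1, max_iters + 1):
        for j, tor in n_side + c_side:
            on_n_side = j <= cutpoint
            if tor == 0:
                origin, axis_to = coords[j, N], coords[j, CA]
            else:
                origin, axis_to = coords[j, CA], coords[j, C]
            axis = axis_to - origin
            if on_n_side:
                blocks = moving_block_n(j, tor)
                mov = anchors_moving
                fix = anchors_fixed
            else:
                blocks = moving_block_c(j, tor)
                if not blocks:
                    continue
                # rotating the C side moves the *targets*: optimal angle is
                # computed with roles swapped
                mov = anchors_fixed
                fix = anchors_moving
            theta = _optimal_rotation(mov, fix, origin, axis)
            theta = float(np.clip(theta, -step_cap, step_cap))
            if abs(theta) < 1e-10:
                continue
            if not on_n_side:
                blocks = blocks + [anchors_fixed]
            flat = np.concatenate(blocks, axis=0)
            rotated = geom.rotate_about_axis(flat, origin, axis, theta)
            pos = 0
            for blk in blocks:
                nrow = len(blk)
                blk[...] = rotated[pos:pos + nrow]
                pos += nrow
        trace.append(dev())
        if trace[-1] <= tol:
            break

    final = trace[-1]
    closed = final <= tol
    model.break_after[cutpoint] = not closed
    model.sync_torsions()
    model._place_oxygen(s, min(e, model.n_res - 1))
    return model, CCDReport(closed, final, it, trace)
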