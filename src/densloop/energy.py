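"""Smooth low-resolution energy model.

A weighted sum of differentiable backbone-level terms:

* ``rama`` — negative log of a periodic mixture of anisotropic Gaussian
  basins (alpha, beta, left-alpha) plus a uniform floor, over (phi, psi).
* ``vdw`` — purely repulsive soft-sphere term over backbone atoms and a
  virtual-CB side-chain interaction centre.
* ``hbond_bb`` — backbone N-H...O=C hydrogen-bond wells (Gaussian in the
  H...O distance, cosine-squared angular switch that vanishes below 90 deg).
* ``cart_bonded`` — harmonic restraints on backbone bond lengths, bond
  angles and omega planarity, including the inter-residue C-N bond, so that
  chain breaks are penalised (and pulled closed by minimization) rather
  than being structurally forbidden.
* ``density`` — the fast unmasked density score from a
  :class:`~densloop.density.SplineScoreField`.

Every term returns ``(energy, gradient)`` with the gradient laid out as
(n_res, 4, 3) over the independent backbone atoms N, CA, C, O; derived atoms
(amide H, virtual CB) are chained back onto these through their closed-form
Jacobians, so the total gradient is analytic throughout.
"""

from __future__ import annotations

import numpy as np
import yaml
from scipy.spatial import cKDTree

from . import constants as k
from . import geometry as geom
from .density import SplineScoreField, fast_density_score
from .model import BackboneModel, N, CA, C, O

_DEG = np.pi / 180.0


def load_weights(path) -> dict[str, float]:
    """Read term weights from a YAML mapping file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    weights = dict(k.DEFAULT_WEIGHTS)
    weights.update({str(key): float(v) for key, v in data.items()})
    return weights


class EnergyModel:
    """Weighted smooth low-resolution energy with analytic gradients.

    Parameters
    ----------
    weights : mapping term name -> nonnegative weight. Missing terms take
        the packaged defaults.
    vdw_scale : multiplies both the repulsion constant and (for values > 1)
        emulates a stiffer, all-atom-like landscape; used for the
        smoothness-comparison experiments.
    """

    TERMS = ("rama", "vdw", "hbond_bb", "cart_bonded", "density")

    def __init__(self, weights: dict[str, float] | None = None,
                 vdw_scale: float = 1.0):
        self.weights = dict(k.DEFAULT_WEIGHTS)
        if weights is not None:
            self.weights.update(weights)
        for term, w in self.weights.items():
            if w < 0:
                raise ValueError(f"negative weight for {term}")
        self.vdw_scale = float(vdw_scale)

    # ------------------------------------------------------------------
    # Ramachandran
    # ------------------------------------------------------------------

    @staticmethod
    def rama_p(phi: np.ndarray, psi: np.ndarray):
        """Mixture density P(phi, psi) and its partials dP/dphi, dP/dpsi
        (per degree). Periodic in both arguments."""
        phi = np.asarray(phi, float)
        psi = np.asarray(psi, float)
        p = np.full(phi.shape, k.RAMA_FLOOR)
        dp_phi = np.zeros_like(p)
        dp_psi = np.zeros_like(p)
        for w, (p0, s0), (sp, ss) in k.RAMA_BASINS:
            dphi = geom.wrap_angle(phi - p0)
            dpsi = geom.wrap_angle(psi - s0)
            g = w * np.exp(-0.5 * ((dphi / sp) ** 2 + (dpsi / ss) ** 2))
            p += g
            dp_phi += g * (-dphi / sp**2)
            dp_psi += g * (-dpsi / ss**2)
        return p, dp_phi, dp_psi

    @staticmethod
    def _bonded_mask(model: BackboneModel) -> np.ndarray:
        """(n-1,) bool: residues i and i+1 chain-bonded (vectorised)."""
        c = model.coords
        nres = model.n_res
        if nres < 2:
            return np.zeros(0, dtype=bool)
        consec = np.diff(model.resnum) == 1
        fin = (np.isfinite(c[:-1, C]).all(axis=1)
               & np.isfinite(c[1:, N]).all(axis=1))
        ok = consec & fin & ~model.break_after[:-1]
        d = np.linalg.norm(np.where(ok[:, None], c[1:, N] - c[:-1, C], 1.0), axis=1)
        return ok & (d > 0.5) & (d < 3.0)

    def rama_energy(self, model: BackboneModel):
        grad = np.zeros((model.n_res, 4, 3))
        c = model.coords
        bonded = self._bonded_mask(model)
        # interior residues bonded on both sides
        idx = np.nonzero(bonded[:-1] & bonded[1:])[0] + 1
        if len(idx) == 0:
            return 0.0, grad
        phi = geom.dihedral(c[idx - 1, C], c[idx, N], c[idx, CA], c[idx, C])
        psi = geom.dihedral(c[idx, N], c[idx, CA], c[idx, C], c[idx + 1, N])
        p, dpf, dps = self.rama_p(phi, psi)
        energy = -float(np.log(p).sum())
        de_dphi = (-dpf / p / _DEG)[:, None]  # per radian
        de_dpsi = (-dps / p / _DEG)[:, None]
        gphi = geom.dihedral_grad(c[idx - 1, C], c[idx, N], c[idx, CA], c[idx, C])
        gpsi = geom.dihedral_grad(c[idx, N], c[idx, CA], c[idx, C], c[idx + 1, N])
        for (off, ai), g in zip(((-1, C), (0, N), (0, CA), (0, C)), gphi):
            np.add.at(grad, (idx + off, ai), de_dphi * g)
        for (off, ai), g in zip(((0, N), (0, CA), (0, C), (1, N)), gpsi):
            np.add.at(grad, (idx + off, ai), de_dpsi * g)
        return energy, grad

    # ------------------------------------------------------------------
    # Soft-sphere repulsion
    # ------------------------------------------------------------------

    def _interaction_atoms(self, model: BackboneModel):
        """Positions/types/residue indices of backbone + virtual-CB centres,
        plus the per-residue CB Jacobians for the chain rule."""
        jacs = geom.virtual_cb_jacobians(
            model.coords[:, N], model.coords[:, CA], model.coords[:, C])
        has = np.isfinite(model.coords[:, :3]).all(axis=(1, 2))
        pos5 = np.concatenate([model.coords, model.virtual_cb()[:, None, :]], axis=1)
        fin = np.isfinite(pos5).all(axis=2) & has[:, None]
        res, types = np.nonzero(fin)
        return pos5[res, types], types, res, jacs

    def _chain_cb(self, grad: np.ndarray, cb_grad: np.ndarray, jacs) -> None:
        """Accumulate d/d(CB) contributions onto N, CA, C via the Jacobians."""
        jn, jca, jc = jacs
        grad[:, N] += np.einsum("ni,nij->nj", cb_grad, jn)
        grad[:, CA] += np.einsum("ni,nij->nj", cb_grad, jca)
        grad[:, C] += np.einsum("ni,nij->nj", cb_grad, jc)

    def vdw_energy(self, model: BackboneModel):
        grad = np.zeros((model.n_res, 4, 3))
        cb_grad = np.zeros((model.n_res, 3))
        pos, types, res, jacs = self._interaction_atoms(model)
        if len(pos) == 0:
            return 0.0, grad
        radii = np.array([k.VDW_RADII[t] for t in ("N", "CA", "C", "O", "CB")])
        r_at = radii[types]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
        if len(pairs) == 0:
            return 0.0, grad
        i, j = pairs[:, 0], pairs[:, 1]
        sep_ok = np.abs(res[i] - res[j]) >= k.VDW_MIN_SEQ_SEP
        i, j = i[sep_ok], j[sep_ok]
        dv = pos[i] - pos[j]
        d = np.linalg.norm(dv, axis=1)
        r0 = r_at[i] + r_at[j]
        clash = d < r0
        if not clash.any():
            return 0.0, grad
        i, j, dv, d, r0 = i[clash], j[clash], dv[clash], d[clash], r0[clash]
        kk = k.VDW_K * self.vdw_scale
        energy = float(np.sum(kk * (r0 - d) ** 2))
        dE_dd = -2.0 * kk * (r0 - d)
        gvec = (dE_dd / d)[:, None] * dv
        for idx, sign in ((i, 1.0), (j, -1.0)):
            backbone = types[idx] < 4
            np.add.at(grad, (res[idx][backbone], types[idx][backbone]),
                      sign * gvec[backbone])
            np.add.at(cb_grad, res[idx][~backbone], sign * gvec[~backbone])
        self._chain_cb(grad, cb_grad, jacs)
        return energy, grad

    # ------------------------------------------------------------------
    # Backbone hydrogen bonds
    # ------------------------------------------------------------------

    def _hbond_pairs(self, model: BackboneModel):
        bonded = self._bonded_mask(model)
        has = np.isfinite(model.coords[:, :3]).all(axis=(1, 2))
        donors = np.nonzero(np.concatenate([[False], bonded]) & has)[0]
        acceptors = np.nonzero(np.isfinite(model.coords[:, O]).all(axis=1))[0]
        return donors, acceptors

    def hbond_bb_energy(self, model: BackboneModel, return_pairs: bool = False):
        grad = np.zeros((model.n_res, 4, 3))
        donors, acceptors = self._hbond_pairs(model)
        empty = (np.zeros(0, int), np.zeros(0, int), np.zeros(0))
        if len(donors) == 0 or len(acceptors) == 0:
            return (0.0, grad, *empty) if return_pairs else (0.0, grad)
        c = model.coords
        n_d = c[donors, N]
        ca_d = c[donors, CA]
        cp_d = c[donors - 1, C]
        h = geom.amide_h(n_d, ca_d, cp_d)
        jh_n, jh_ca, jh_cp = geom.amide_h_jacobians(n_d, ca_d, cp_d)
        o_pos = c[acceptors, O]
        # candidate pairs within the distance cutoff
        diff = h[:, None, :] - o_pos[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        sep = np.abs(donors[:, None] - acceptors[None, :])
        di, aj = np.nonzero((d < k.HBOND_CUTOFF) & (sep >= k.HBOND_MIN_SEQ_SEP))
        if len(di) == 0:
            return (0.0, grad, *empty) if return_pairs else (0.0, grad)
        dd = d[di, aj]
        u = diff[di, aj] / dd[:, None]          # unit H->O reversed: (H-O)/d
        gauss = np.exp(-0.5 * ((dd - k.HBOND_D0) / k.HBOND_SIGMA) ** 2)
        a_vec = n_d[di] - h[di]
        b_vec = o_pos[aj] - h[di]
        na = np.linalg.norm(a_vec, axis=1)
        nb = np.linalg.norm(b_vec, axis=1)
        cos = np.sum(a_vec * b_vec, axis=1) / (na * nb)
        sw = np.maximum(0.0, -cos)
        pair_e = -k.HBOND_DEPTH * gauss * sw**2
        energy = float(pair_e.sum())
        # gradients
        dG_dd = gauss * (-(dd - k.HBOND_D0) / k.HBOND_SIGMA**2)
        dE_dd = -k.HBOND_DEPTH * sw**2 * dG_dd
        ds_dcos = -2.0 * sw
        dE_dcos = -k.HBOND_DEPTH * gauss * ds_dcos
        dcos_da = (b_vec / (na * nb)[:, None]
                   - (cos / na**2)[:, None] * a_vec)
        dcos_db = (a_vec / (na * nb)[:, None]
                   - (cos / nb**2)[:, None] * b_vec)
        g_h = dE_dd[:, None] * u + dE_dcos[:, None] * (-dcos_da - dcos_db)
        g_o = -dE_dd[:, None] * u + dE_dcos[:, None] * dcos_db
        g_n = dE_dcos[:, None] * dcos_da
        np.add.at(grad, (acceptors[aj], O), g_o)
        np.add.at(grad, (donors[di], N), g_n)
        # chain H back to N, CA, C(prev)
        np.add.at(grad, (donors[di], N), np.einsum("mi,mij->mj", g_h, jh_n[di]))
        np.add.at(grad, (donors[di], CA), np.einsum("mi,mij->mj", g_h, jh_ca[di]))
        np.add.at(grad, (donors[di] - 1, C), np.einsum("mi,mij->mj", g_h, jh_cp[di]))
        if return_pairs:
            return energy, grad, donors[di], acceptors[aj], pair_e
        return energy, grad

    def count_hbonds(self, model: BackboneModel,
                     threshold: float = -0.1) -> int:
        """Number of donor-acceptor pairs with well energy below
        ``threshold`` (in units of the well depth)."""
        out = self.hbond_bb_energy(model, return_pairs=True)
        pair_e = out[4]
        return int(np.sum(pair_e < threshold * k.HBOND_DEPTH))

    # ------------------------------------------------------------------
    # Bond-geometry restraints
    # ------------------------------------------------------------------

    def cart_bonded_energy(self, model: BackboneModel):
        grad = np.zeros((model.n_res, 4, 3))
        energy = 0.0
        c = model.coords
        has = np.array([model.has_coords(i) for i in range(model.n_res)])
        has_o = has & np.isfinite(c[:, O]).all(axis=1)
        intra = np.nonzero(has)[0]
        with_o = np.nonzero(has_o)[0]
        # consecutive-numbered neighbours with coordinates on both sides:
        # restrained regardless of recorded breaks, so that open junctions
        # are penalised and pulled closed by minimization.
        if model.n_res > 1:
            consec = (np.diff(model.resnum) == 1) & has[:-1] & has[1:]
            inter = np.nonzero(consec)[0]
            inter_o = np.nonzero(consec & has_o[:-1])[0]
        else:
            inter = inter_o = np.zeros(0, dtype=int)

        def bonds(i1, s1, i2, s2, ideal):
            nonlocal energy
            if len(i1) == 0:
                return
            dv = c[i1, s1] - c[i2, s2]
            d = np.linalg.norm(dv, axis=1)
            dev = d - ideal
            energy += k.CART_K_LENGTH * float(np.sum(dev**2))
            g = (2.0 * k.CART_K_LENGTH * dev / d)[:, None] * dv
            np.add.at(grad, (i1, s1), g)
            np.add.at(grad, (i2, s2), -g)

        def angles(atoms, ideal_deg):
            nonlocal energy
            (i1, s1), (i2, s2), (i3, s3) = atoms
            if len(i1) == 0:
                return
            pts = (c[i1, s1], c[i2, s2], c[i3, s3])
            dev = np.radians(geom.bond_angle(*pts) - ideal_deg)
            energy += k.CART_K_ANGLE * float(np.sum(dev**2))
            gs = geom.bond_angle_grad(*pts)
            coef = (2.0 * k.CART_K_ANGLE * dev)[:, None]
            for (ii, ss), g in zip(atoms, gs):
                np.add.at(grad, (ii, ss), coef * g)

        bonds(intra, CA, intra, N, k.BOND_N_CA)
        bonds(intra, C, intra, CA, k.BOND_CA_C)
        bonds(with_o, O, with_o, C, k.BOND_C_O)
        bonds(inter + 1, N, inter, C, k.BOND_C_N)
        angles(((intra, N), (intra, CA), (intra, C)), k.ANGLE_N_CA_C)
        angles(((with_o, CA), (with_o, C), (with_o, O)), k.ANGLE_CA_C_O)
        angles(((inter, CA), (inter, C), (inter + 1, N)), k.ANGLE_CA_C_N)
        angles(((inter, C), (inter + 1, N), (inter + 1, CA)), k.ANGLE_C_N_CA)
        angles(((inter_o, O), (inter_o, C), (inter_o + 1, N)), k.ANGLE_O_C_N)
        if len(inter):
            pts = (c[inter, CA], c[inter, C], c[inter + 1, N], c[inter + 1, CA])
            dev = np.radians(geom.wrap_angle(geom.dihedral(*pts) - k.OMEGA_IDEAL))
            energy += k.CART_K_OMEGA * float(np.sum(dev**2))
            gs = geom.dihedral_grad(*pts)
            coef = (2.0 * k.CART_K_OMEGA * dev)[:, None]
            for (off, ss), g in zip(((0, CA), (0, C), (1, N), (1, CA)), gs):
                np.add.at(grad, (inter + off, ss), coef * g)
        return energy, grad

    # ------------------------------------------------------------------
    # Density term
    # ------------------------------------------------------------------

    def density_energy(self, model: BackboneModel, field: SplineScoreField):
        score, g5 = fast_density_score(model, field)
        grad = np.zeros((model.n_res, 4, 3))
        grad += g5[:, :4]
        cb_grad = g5[:, 4]
        jacs = geom.virtual_cb_jacobians(
            model.coords[:, N], model.coords[:, CA], model.coords[:, C])
        finite = np.isfinite(cb_grad).all(axis=1)
        cb_grad = np.where(finite[:, None], cb_grad, 0.0)
        self._chain_cb(grad, cb_grad, jacs)
        return score, grad

    # ------------------------------------------------------------------

    def total_energy(self, model: BackboneModel,
                     field: SplineScoreField | None = None):
        """Weighted total energy and gradient over all enabled terms."""
        w = self.weights
        if w.get("density", 0.0) > 0 and field is None:
            raise ValueError("density weight > 0 but no score field given")
        energy = 0.0
        grad = np.zeros((model.n_res, 4, 3))
        for name, fn in (("rama", self.rama_energy),
                         ("vdw", self.vdw_energy),
                         ("hbond_bb", self.hbond_bb_energy),
                         ("cart_bonded", self.cart_bonded_energy)):
            if w.get(name, 0.0) != 0.0:
                e, g = fn(model)
                energy += w[name] * e
                grad += w[name] * g
        if w.get("density", 0.0) != 0.0:
            e, g = self.density_energy(model, field)
            energy += w["density"] * e
            grad += w["density"] * g
        if not np.isfinite(energy):
            raise FloatingPointError("non-finite total energy")
        return energy, grad
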