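"""Low-resolution energy terms: analytic gradients vs finite differences,
closed-form values, rigid-motion invariance and smoothness."""

import numpy as np
import pytest

from densloop import constants as k
from densloop import density as D
from densloop.energy import EnergyModel, load_weights
from densloop.model import BackboneModel

from conftest import ideal_chain


@pytest.fixture(scope="module")
def em():
    return EnergyModel()


@pytest.fixture(scope="module")
def crumpled():
    """A distorted helix with contacts, H-bonds and off-ideal geometry."""
    rng = np.random.default_rng(0)
    tors = np.tile([-57.0, -47.0, 180.0], (14, 1)) + rng.normal(0, 8, (14, 3))
    m = BackboneModel.from_torsions("A" * 14, tors)
    m.coords += rng.normal(0, 0.1, m.coords.shape)
    m.detect_breaks()
    return m


def fd_max_error(model, fn, n_checks=25, h=1e-4, seed=1):
    """Max |analytic - central-difference| gradient component, relative to
    the gradient scale."""
    _, grad = fn(model)
    idxs = list(zip(*np.nonzero(np.isfinite(model.coords))))
    rng = np.random.default_rng(seed)
    sel = [idxs[i] for i in rng.choice(len(idxs), size=min(n_checks, len(idxs)),
                                      replace=False)]
    scale = max(np.abs(grad).max(), 1.0)
    worst = 0.0
    for (i, s, d) in sel:
        mp, mm = model.copy(), model.copy()
        mp.coords[i, s, d] += h
        mm.coords[i, s, d] -= h
        fd = (fn(mp)[0] - fn(mm)[0]) / (2 * h)
        worst = max(worst, abs(fd - grad[i, s, d]) / scale)
    return worst


class TestGradients:
    @pytest.mark.parametrize("term", ["rama", "vdw", "hbond_bb", "cart_bonded"])
    def test_term_gradients(self, em, term, crumpled):
        fn = {"rama": em.rama_energy, "vdw": em.vdw_energy,
              "hbond_bb": em.hbond_bb_energy,
              "cart_bonded": em.cart_bonded_energy}[term]
        assert fd_max_error(crumpled, fn) < 1e-4

    @pytest.mark.parametrize("seed", range(5))
    def test_total_gradient_random_conformations(self, em, seed):
        rng = np.random.default_rng(seed)
        n = 12
        tors = np.column_stack([rng.uniform(-170, -40, n),
                                rng.uniform(-60, 160, n),
                                rng.normal(180, 5, n)])
        m = BackboneModel.from_torsions("A" * n, tors)
        m.coords += rng.normal(0, 0.05, m.coords.shape)
        m.detect_breaks()
        dmap = D.simulate_map(m, 0.6, 3.0)
        field = D.build_spline_field(dmap)
        assert fd_max_error(m, lambda mm: em.total_energy(mm, field),
                            n_checks=15) < 1e-4


class TestRama:
    def test_alpha_basin_beats_disallowed(self, em):
        p_alpha, _, _ = em.rama_p(-63.0, -43.0)
        p_bad, _, _ = em.rama_p(60.0, -60.0)
        assert -np.log(p_alpha) < -np.log(p_bad) - 2.0

    def test_periodicity(self, em):
        p1, _, _ = em.rama_p(-63.0, -43.0)
        p2, _, _ = em.rama_p(-63.0 + 360.0, -43.0)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_gradient_vanishes_at_basin_centre(self, em):
        _, dphi, dpsi = em.rama_p(-63.0, -43.0)
        assert abs(dphi) < 1e-6 and abs(dpsi) < 1e-6


class TestVdw:
    def test_extended_chain_no_contacts(self, em):
        m = ideal_chain(10, phi_psi=(-120.0, 120.0))
        e, grad = em.vdw_energy(m)
        assert e == 0.0
        assert not np.any(grad)

    def test_pair_at_half_radius_closed_form(self, em):
        # two chains far apart except one forced contact
        m = ideal_chain(6, phi_psi=(-120.0, 120.0))
        m2 = m.copy()
        # place residue 5's N at half the N..N contact radius from residue 1's N
        r0 = 2 * k.VDW_RADII["N"]
        m2.coords[5] += (m2.coords[1, 0] + np.array([r0 / 2, 0, 0])
                         - m2.coords[5, 0])
        m2.detect_breaks()
        e, _ = em.vdw_energy(m2)
        contrib = k.VDW_K * (r0 / 2) ** 2
        # the forced N..N pair dominates; other atoms of residue 5 may touch
        assert e >= contrib - 1e-9
        assert fd_max_error(m2, em.vdw_energy) < 1e-4


class TestHbond:
    def test_helix_has_i_i4_ladder(self, em):
        L = 12
        m = ideal_chain(L)
        e, _ = em.hbond_bb_energy(m)
        assert e < 0
        n_wells = em.count_hbonds(m)
        assert abs(n_wells - (L - 4)) <= 1

    def test_extended_strand_is_zero(self, em):
        m = ideal_chain(12, phi_psi=(-120.0, 120.0))
        e, _ = em.hbond_bb_energy(m)
        assert abs(e) < 1e-6

    def test_expansion_kills_all_wells(self, em):
        m = ideal_chain(12)
        m.coords *= 2.0
        m.break_after[:] = False
        m.detect_breaks()
        e, _ = em.hbond_bb_energy(m)
        assert abs(e) < 1e-6


class TestCartBonded:
    def test_ideal_chain_scores_zero(self, em):
        m = ideal_chain(10)
        e, _ = em.cart_bonded_energy(m)
        assert e < 1e-8

    def test_stretched_bond_closed_form(self, em):
        m = ideal_chain(6)
        direction = m.coords[3, 0] - m.coords[2, 2]
        direction /= np.linalg.norm(direction)
        m.coords[3:] += 0.5 * direction  # stretch one C-N bond by +0.5 A
        e, _ = em.cart_bonded_energy(m)
        # bond term exactly k*0.25; angles/omega unchanged by pure stretch
        assert e == pytest.approx(k.CART_K_LENGTH * 0.25, rel=1e-6)

    def test_noise_restoration_by_minimization(self, em):
        from densloop.minimize import cartesian_minimize
        rng = np.random.default_rng(5)
        m = ideal_chain(12)
        m.coords += rng.normal(0, 0.3, m.coords.shape)
        m.break_after[:] = False
        m.detect_breaks()
        only_cart = EnergyModel({"rama": 0, "vdw": 0, "hbond_bb": 0,
                                 "density": 0})
        mn, _ = cartesian_minimize(m, only_cart, max_evals=3000)
        assert mn.bond_length_deviations().max() < 0.02


class TestTotal:
    def test_zero_weights_zero_energy(self, crumpled):
        em0 = EnergyModel({t: 0.0 for t in EnergyModel.TERMS})
        e, grad = em0.total_energy(crumpled)
        assert e == 0.0 and not np.any(grad)

    def test_single_term_equals_component(self, crumpled):
        em1 = EnergyModel({"rama": 1.0, "vdw": 0, "hbond_bb": 0,
                           "cart_bonded": 0, "density": 0})
        e, grad = em1.total_energy(crumpled)
        er, gr = em1.rama_energy(crumpled)
        assert e == pytest.approx(er)
        assert np.allclose(grad, gr)

    def test_weight_homogeneity(self, crumpled):
        w = {"rama": 0.5, "vdw": 1.0, "hbond_bb": 1.0, "cart_bonded": 1.0,
             "density": 0}
        e1, g1 = EnergyModel(w).total_energy(crumpled)
        e2, g2 = EnergyModel({t: 2 * v for t, v in w.items()}).total_energy(crumpled)
        assert e2 == pytest.approx(2 * e1)
        assert np.allclose(g2, 2 * g1)

    def test_density_weight_without_field_errors(self, crumpled):
        with pytest.raises(ValueError):
            EnergyModel().total_energy(crumpled, None)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            EnergyModel({"vdw": -1.0})


class TestInvariance:
    @pytest.mark.parametrize("term", ["rama", "vdw", "hbond_bb", "cart_bonded"])
    def test_rigid_motion_invariance(self, em, crumpled, term):
        from scipy.spatial.transform import Rotation
        fn = {"rama": em.rama_energy, "vdw": em.vdw_energy,
              "hbond_bb": em.hbond_bb_energy,
              "cart_bonded": em.cart_bonded_energy}[term]
        e0, _ = fn(crumpled)
        rot = Rotation.random(random_state=11).as_matrix()
        moved = crumpled.copy()
        moved.coords = crumpled.coords @ rot.T + np.array([5.0, -3.0, 2.0])
        e1, _ = fn(moved)
        assert e1 == pytest.approx(e0, abs=1e-8 * max(1, abs(e0)))

    def test_smooth_along_interpolation(self, em):
        rng = np.random.default_rng(9)
        a = ideal_chain(10, noise=25.0, rng=1)
        b = ideal_chain(10, phi_psi=(-120.0, 120.0), noise=25.0, rng=2)
        for lam in np.linspace(0, 1, 1000):
            m = a.copy()
            m.coords = (1 - lam) * a.coords + lam * b.coords
            e, g = EnergyModel({"density": 0}).total_energy(m)
            assert np.isfinite(e) and np.all(np.isfinite(g))


def test_load_weights_yaml(tmp_path):
    path = tmp_path / "w.yaml"
    path.write_text("rama: 0.25\ndensity: 0.0\n")
    w = load_weights(path)
    assert w["rama"] == 0.25
    assert w["density"] == 0.0
    assert w["vdw"] == k.DEFAULT_WEIGHTS["vdw"]
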