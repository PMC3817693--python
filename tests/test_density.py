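"""Density simulation, masked correlation, and the fast FFT-convolution
score field with its spline gradients."""

import time

import numpy as np
import pytest
from scipy import stats

from densloop import density as D
from densloop import constants as k
from conftest import ideal_chain


@pytest.fixture(scope="module")
def helix_map():
    model = ideal_chain(20)
    dmap = D.simulate_map(model, 0.5, 3.0, padding=6.0)
    return model, dmap


@pytest.fixture(scope="module")
def field(helix_map):
    _, dmap = helix_map
    return D.build_spline_field(dmap)


class TestSimulateMap:
    def test_single_atom_peak_at_grid_node(self):
        m = ideal_chain(1)
        m.coords[0, 1] = np.round(m.coords[0, 1])
        dmap = D.simulate_map(m, 1.0, 3.0, padding=5.0)
        # the maximum voxel is a grid node nearest to the heaviest overlap
        peak = np.unravel_index(np.argmax(dmap.values), dmap.shape)
        world = dmap.grid_to_world(peak)
        atoms = np.vstack([m.coords[0, :4], m.virtual_cb()[0]])
        assert np.linalg.norm(world - atoms, axis=1).min() < 1.01

    def test_on_grid_translation_equivariance(self):
        m1 = ideal_chain(1)
        dmap1 = D.simulate_map(m1, 1.0, 3.0, padding=5.0)
        m2 = m1.copy()
        m2.coords += np.array([1.0, 0.0, 0.0])  # exactly one grid step
        dmap2 = D.DensityMap(np.zeros(dmap1.shape), dmap1.spacing,
                             dmap1.origin, 3.0)
        dmap2 = D.simulate_on_grid(m2, dmap2)
        assert np.allclose(dmap2.values[1:], dmap1.values[:-1], atol=1e-12)

    def test_total_mass_matches_amplitudes(self, helix_map):
        model, dmap = helix_map
        integral = dmap.values.sum() * np.prod(dmap.spacing)
        expected = sum(k.ATOM_ELECTRONS.values()) * model.n_res
        assert integral == pytest.approx(expected, rel=0.02)

    def test_nyquist_guard(self):
        with pytest.raises(ValueError, match="resolution/3"):
            D.simulate_map(ideal_chain(3), 2.0, 3.0)


class TestMaskedCC:
    def test_self_correlation_is_one(self, helix_map):
        model, dmap = helix_map
        per_res, total = D.masked_residue_cc(model, dmap)
        assert np.nanmin(per_res) > 1.0 - 1e-6
        assert total == pytest.approx(-1.0, abs=1e-6)

    def test_negated_map_anticorrelates(self, helix_map):
        model, dmap = helix_map
        neg = D.DensityMap(-dmap.values, dmap.spacing, dmap.origin, 3.0)
        per_res, _ = D.masked_residue_cc(model, neg)
        assert np.nanmax(per_res) < -1.0 + 1e-6

    def test_displaced_model_scores_poorly(self, helix_map):
        model, dmap = helix_map
        off = model.copy()
        off.coords += 10.0
        per_res, total = D.masked_residue_cc(off, dmap)
        # frozen from the computed value (0.24) on this fixture
        assert -total < 0.3


class TestSplineField:
    def test_matches_brute_force_convolution(self, helix_map, field):
        _, dmap = helix_map
        rng = np.random.default_rng(0)
        extent = np.asarray(dmap.shape) * dmap.spacing
        pts = dmap.origin + 4.0 + rng.random((200, 3)) * (extent - 8.0)
        ker = D.default_kernels(3.0)["C"]
        ax = [np.arange(s) * dmap.spacing[d] + dmap.origin[d]
              for d, s in enumerate(dmap.shape)]
        ref = np.empty(len(pts))
        for i, p in enumerate(pts):
            r2 = ((ax[0] - p[0])[:, None, None] ** 2
                  + (ax[1] - p[1])[None, :, None] ** 2
                  + (ax[2] - p[2])[None, None, :] ** 2)
            ref[i] = np.sum(ker.real_space(r2) * dmap.values) \
                * np.prod(dmap.spacing)
        val = field.interpolate("C", pts, with_gradient=False)
        assert np.abs(val - ref).max() / np.abs(ref).max() < 1e-3

    def test_gradient_matches_finite_differences(self, helix_map, field):
        _, dmap = helix_map
        rng = np.random.default_rng(1)
        extent = np.asarray(dmap.shape) * dmap.spacing
        pts = dmap.origin + 4.0 + rng.random((100, 3)) * (extent - 8.0)
        _, grad = field.interpolate("O", pts)
        h = 0.01
        for d in range(3):
            pp, pm = pts.copy(), pts.copy()
            pp[:, d] += h
            pm[:, d] -= h
            fd = (field.interpolate("O", pp, with_gradient=False)
                  - field.interpolate("O", pm, with_gradient=False)) / (2 * h)
            scale = np.abs(grad[:, d]).max()
            assert np.abs(fd - grad[:, d]).max() / scale < 1e-4

    def test_interpolation_exact_at_nodes(self, field):
        nodes = np.stack(np.meshgrid(*[np.arange(5, 11)] * 3,
                                     indexing="ij"), -1).reshape(-1, 3)
        world = field.origin + nodes * field.spacing
        stored = field.node_values["N"][nodes[:, 0], nodes[:, 1], nodes[:, 2]]
        interp = field.interpolate("N", world, with_gradient=False)
        assert np.abs(stored - interp).max() < 1e-8 * np.abs(stored).max()

    def test_delta_map_reproduces_kernel(self):
        # 0.5 A sampling keeps the band-limiting error of the spectral
        # convolution far below the comparison tolerance
        vals = np.zeros((36, 36, 36))
        vals[18, 18, 18] = 1.0 / 0.5**3  # unit point mass
        dmap = D.DensityMap(vals, [0.5] * 3, [0.0] * 3, 3.0)
        field = D.build_spline_field(dmap)
        ker = D.default_kernels(3.0)["CA"]
        centre = dmap.grid_to_world((18, 18, 18))
        rng = np.random.default_rng(2)
        pts = centre + rng.normal(0, 1.0, (50, 3))
        expected = ker.real_space(np.sum((pts - centre) ** 2, axis=1))
        got = field.interpolate("CA", pts, with_gradient=False)
        assert np.abs(got - expected).max() < 1e-3 * expected.max()

    def test_uniform_map_gives_kernel_integral(self):
        c = 2.5
        dmap = D.DensityMap(np.full((20, 20, 20), c), [1.0] * 3, [0.0] * 3, 3.0)
        field = D.build_spline_field(dmap)
        ker = D.default_kernels(3.0)["CB"]
        pts = np.array([[8.0, 9.0, 10.0], [10.3, 9.7, 8.1]])
        got = field.interpolate("CB", pts, with_gradient=False)
        assert np.allclose(got, c * ker.amplitude, rtol=1e-6)


class TestFastScore:
    def test_true_pose_beats_shifted(self, helix_map, field):
        model, _ = helix_map
        s0, _ = D.fast_density_score(model, field)
        shifted = model.copy()
        shifted.coords += 2.0
        s1, _ = D.fast_density_score(shifted, field)
        assert s0 < s1

    def test_empty_model_scores_zero(self, helix_map, field):
        model, _ = helix_map
        empty = model.copy()
        empty.coords[:] = np.nan
        score, grads = D.fast_density_score(empty, field)
        assert score == 0.0
        assert not np.any(grads)

    def test_rank_agreement_with_global_cc(self, helix_map, field):
        """Fast score ordering tracks the unmasked Pearson CC ordering."""
        model, dmap = helix_map
        rng = np.random.default_rng(3)
        fast_scores, ccs = [], []
        for _ in range(50):
            pert = model.copy()
            pert.coords += rng.normal(0, rng.uniform(0.05, 1.2),
                                      pert.coords.shape)
            s, _ = D.fast_density_score(pert, field)
            calc = D.simulate_on_grid(pert, dmap)
            cc = np.corrcoef(calc.values.ravel(), dmap.values.ravel())[0, 1]
            fast_scores.append(s)
            ccs.append(-cc)
        rho = stats.spearmanr(fast_scores, ccs).statistic
        assert rho >= 0.9

    def test_cost_independent_of_map_size(self):
        """Per-call cost after field construction is linear in atoms and far
        cheaper than the masked correlation."""
        model = ideal_chain(100)
        dmap = D.simulate_map(model, 1.0, 3.0)
        field = D.build_spline_field(dmap)
        D.fast_density_score(model, field)  # warm up
        t0 = time.perf_counter()
        for _ in range(5):
            D.fast_density_score(model, field)
        t_fast = (time.perf_counter() - t0) / 5
        t0 = time.perf_counter()
        D.masked_residue_cc(model, dmap)
        t_masked = time.perf_counter() - t0
        assert t_masked / t_fast > 5.0


def test_kernel_integral_on_grid():
    ker = D.AtomKernel.for_resolution("C", 3.0)
    ax = np.arange(-6, 6.01, 0.25)
    r2 = (ax[:, None, None] ** 2 + ax[None, :, None] ** 2
          + ax[None, None, :] ** 2)
    integral = ker.real_space(r2).sum() * 0.25**3
    assert integral == pytest.approx(ker.amplitude, rel=0.01)
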