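"""The fixture generator: topology building, template corruption, noise
calibration and benchmark determinism."""

import filecmp
import os

import numpy as np
import pytest

from densloop.energy import EnergyModel
from densloop.evaluate import model_map_cc
from densloop.synthetic import (make_benchmark, make_noisy_map, make_template,
                                make_topology)


@pytest.fixture(scope="module")
def em():
    return EnergyModel({"density": 0})


class TestTopology:
    def test_h12_is_a_hydrogen_bonded_helix(self, em):
        m = make_topology("H12", np.random.default_rng(0))
        assert em.count_hbonds(m) >= 7

    def test_seeded_generation_is_deterministic(self):
        m1 = make_topology("H8-L4-E6", np.random.default_rng(7))
        m2 = make_topology("H8-L4-E6", np.random.default_rng(7))
        assert np.array_equal(m1.coords, m2.coords)

    def test_short_loop_has_no_clashes(self):
        m = make_topology("L3", np.random.default_rng(1), relax=False)
        vdw = EnergyModel({"rama": 0, "hbond_bb": 0, "cart_bonded": 0,
                           "density": 0})
        assert vdw.total_energy(m)[0] == 0.0

    def test_hairpin_element_pairs_strands(self, em):
        m = make_topology("E8-T2-E8", np.random.default_rng(3))
        # cross-strand wells (sequence separation > 4)
        _, _, di, aj, pe = em.hbond_bb_energy(m, return_pairs=True)
        cross = np.sum((pe < -0.1) & (np.abs(di - aj) > 4))
        assert cross >= 4

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            make_topology("H12-Q4", np.random.default_rng(0))


class TestTemplate:
    @pytest.fixture(scope="class")
    def truth(self):
        return make_topology("H10-L8-H10", np.random.default_rng(11))

    def test_no_perturbation_is_identity(self, truth):
        template, aln = make_template(truth)
        assert np.array_equal(template.coords, truth.coords)
        assert aln.gap_segments == []
        assert len(aln.aligned_pairs) == truth.n_res

    def test_deletion_creates_gap_segment(self, truth):
        template, aln = make_template(truth, delete_segment=(13, 18))
        assert aln.gap_segments == [(13, 18, 6)]
        assert template.n_res == truth.n_res - 6

    def test_loop_shift_moves_loop_only(self, truth):
        template, aln = make_template(truth, loop_shift=(11, 18, 4.0),
                                      rng=np.random.default_rng(0))
        loop = slice(10, 18)
        core = np.ones(truth.n_res, bool)
        core[loop] = False
        loop_rmsd = np.sqrt(np.mean(np.sum(
            (template.coords[loop, 1] - truth.coords[loop, 1]) ** 2, axis=1)))
        core_rmsd = np.sqrt(np.nanmean(np.sum(
            (template.coords[core, 1] - truth.coords[core, 1]) ** 2, axis=1)))
        assert loop_rmsd >= 3.5
        assert core_rmsd < 0.1

    def test_oversized_shift_rejected(self, truth):
        with pytest.raises(ValueError):
            make_template(truth, register_shift=(2, truth.n_res))


class TestNoisyMap:
    @pytest.fixture(scope="class")
    def truth(self):
        return make_topology("H14-L4-H10", np.random.default_rng(21))

    def test_clean_unbiased_map_correlates_perfectly(self, truth):
        dmap = make_noisy_map(truth, None, 3.0, bias_fraction=0.0,
                              rng=np.random.default_rng(0))
        assert model_map_cc(truth, dmap, 3.0) > 1 - 1e-6

    def test_pure_bias_equals_template_density(self, truth):
        template, _ = make_template(truth, loop_shift=(15, 18, 5.0),
                                    rng=np.random.default_rng(1))
        dmap = make_noisy_map(truth, template, 3.0, bias_fraction=1.0,
                              rng=np.random.default_rng(0))
        assert model_map_cc(template, dmap, 3.0) > 1 - 1e-6

    def test_target_cc_bisection(self, truth):
        dmap = make_noisy_map(truth, None, 3.0, bias_fraction=0.0,
                              target_cc=0.30, rng=np.random.default_rng(2))
        assert 0.28 <= model_map_cc(truth, dmap, 3.0) <= 0.32

    def test_unreachable_target_reports_range(self, truth):
        template, _ = make_template(truth, loop_shift=(15, 18, 6.0),
                                    rng=np.random.default_rng(3))
        with pytest.raises(ValueError, match="achievable"):
            make_noisy_map(truth, template, 3.0, bias_fraction=0.9,
                           target_cc=0.999, rng=np.random.default_rng(0))


class TestBenchmark:
    def test_cases_validate(self, benchmark):
        for case in benchmark.values():
            case.truth.validate()
            case.template.validate()
            assert len(case.alignment.gap_segments) == 1
            assert 0.3 <= case.input_cc <= 0.5
            assert len(case.library.of_length(3)) > 0
            assert len(case.library.of_length(9)) > 0

    def test_library_contains_near_native(self, benchmark):
        from densloop.model import torsion_rmsd
        for case in benchmark.values():
            gs, ge, _ = case.alignment.gap_segments[0]
            found = False
            for f in case.library.of_length(9):
                if not f.source_id.startswith("native"):
                    continue
                w = f.window_start
                if w + 8 < gs - 1 or w > ge - 1:
                    continue
                native = np.where(
                    np.isfinite(case.truth.torsions[w:w + 9]),
                    case.truth.torsions[w:w + 9], 180.0)
                if torsion_rmsd(f.torsion_array(), native) < 10.0:
                    found = True
            assert found, case.name

    def test_written_case_files_are_reproducible(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_benchmark(seed=3, out_dir=str(d1), cases=("gap",))
        make_benchmark(seed=3, out_dir=str(d2), cases=("gap",))
        files = sorted(os.listdir(d1 / "gap"))
        assert files == sorted(os.listdir(d2 / "gap"))
        for f in files:
            assert filecmp.cmp(d1 / "gap" / f, d2 / "gap" / f, shallow=False), f

    def test_written_files_parse_back(self, tmp_path, benchmark):
        from densloop import io as dio
        from densloop.fragments import read_library
        from densloop.synthetic import _write_case
        case = benchmark["gap"]
        _write_case(case, str(tmp_path / "gap"))
        m = dio.read_pdb(tmp_path / "gap" / "truth.pdb")
        assert m.n_res == case.truth.n_res
        dmap = dio.read_map(tmp_path / "gap" / "map.mrc")
        assert dmap.shape == case.observed.shape
        aln = dio.read_alignment(tmp_path / "gap" / "align.aln")
        assert aln.gap_segments == case.alignment.gap_segments
        lib = read_library(tmp_path / "gap" / "frags.lib")
        assert len(lib) == len(case.library)

    def test_solvable_with_oracle_fragment_and_clean_map(self, benchmark):
        """Rebuilding the gap with near-native fragments against a clean
        map reaches CC > 0.95 to the truth density."""
        from densloop.density import simulate_map
        from densloop.rebuild import LoopRebuilder
        from conftest import fast_config
        case = benchmark["gap"]
        clean = make_noisy_map(case.truth, None, 3.0, bias_fraction=0.0,
                               rng=np.random.default_rng(0))
        rebuilder = LoopRebuilder(case.template, case.alignment, clean,
                                  case.library,
                                  config=fast_config("2011", n_cycles=30))
        res = rebuilder.fit(seed=0)
        truth_map = simulate_map(case.truth, 1.0, 3.0)
        assert model_map_cc(res.model, truth_map) > 0.95
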