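"""Threading, Metropolis statistics, determinism and the protocol
movability contracts of the rebuild driver."""

import numpy as np
import pytest

from densloop.model import AlignmentSpec
from densloop.rebuild import (LoopRebuilder, RebuildConfig, metropolis_accept,
                              run_rebuild, thread_template)

from conftest import fast_config, ideal_chain


class TestThreading:
    def test_identity_alignment_is_identity(self):
        t = ideal_chain(12, seq="ACDEFGHIKLMN")
        aln = AlignmentSpec("ACDEFGHIKLMN", "ACDEFGHIKLMN",
                            [(i, i) for i in range(1, 13)])
        out = thread_template(t, aln)
        assert np.array_equal(out.coords, t.coords)
        assert "".join(out.seq) == "ACDEFGHIKLMN"

    def test_omitted_residues_leave_gap_segment(self):
        t = ideal_chain(15, seq="A" * 15)
        pairs = [(i, i) for i in range(1, 10)] + [(i - 5, i) for i in range(15, 21)]
        aln = AlignmentSpec("A" * 15, "A" * 20, pairs)
        out = thread_template(t, aln)
        assert not any(10 <= r <= 14 for r in out.resnum)
        assert aln.gap_segments == [(10, 14, 5)]

    def test_mutation_to_target_identity(self):
        t = ideal_chain(6, seq="AAAAAA")
        aln = AlignmentSpec("AAAAAA", "WWWWWW", [(i, i) for i in range(1, 7)])
        out = thread_template(t, aln)
        assert "".join(out.seq) == "WWWWWW"

    def test_bad_reference_rejected(self):
        t = ideal_chain(5)
        with pytest.raises(ValueError):
            thread_template(t, AlignmentSpec("A" * 9, "A" * 9,
                                             [(i, i) for i in range(1, 10)]))

    def test_register_shift_threading(self, benchmark):
        case = benchmark["register"]
        out = thread_template(case.template, case.alignment)
        m, k = 32, 2
        # shifted region carries the template coordinates k residues back
        for q in range(m + k, case.truth.n_res + 1):
            qi = out.index_of(q)
            ti = case.template.index_of(q - k)
            assert np.allclose(out.coords[qi], case.template.coords[ti])


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(metropolis_accept(-abs(rng.normal()), 1.0, rng)
                   for _ in range(100))

    def test_zero_temperature_rejects_uphill(self):
        rng = np.random.default_rng(0)
        assert not metropolis_accept(0.1, 0.0, rng)
        assert metropolis_accept(-0.1, 0.0, rng)

    @pytest.mark.parametrize("delta,temp", [(1.0, 2.0), (0.5, 1.0), (3.0, 2.0)])
    def test_acceptance_frequency_matches_boltzmann(self, delta, temp):
        rng = np.random.default_rng(123)
        n = 10_000
        accepted = sum(metropolis_accept(delta, temp, rng) for _ in range(n))
        p = np.exp(-delta / temp)
        se = np.sqrt(p * (1 - p) / n)
        assert abs(accepted / n - p) < 3 * se


class TestDriver:
    def test_gap_free_run_is_final_minimize_only(self, benchmark):
        case = benchmark["gap"]
        aln = AlignmentSpec("".join(case.truth.seq), "".join(case.truth.seq),
                            [(i, i) for i in range(1, case.truth.n_res + 1)])
        cfg = fast_config("2011", final_min_evals=50)
        traj = run_rebuild(case.truth, aln, case.library, case.observed, cfg)
        assert traj.records == []
        assert traj.acceptance_rate == 0.0

    def test_long_gap_left_broken_with_warning(self, benchmark):
        case = benchmark["gap"]
        cfg = fast_config("2011", max_gap_len=2, final_min_evals=50)
        traj = run_rebuild(case.template, case.alignment, case.library,
                           case.observed, cfg)
        assert any("max_gap_len" in w for w in traj.warnings)
        gs, ge, _ = case.alignment.gap_segments[0]
        assert not any(gs <= r <= ge for r in
                       traj.final_model.resnum[
                           [i for i in range(traj.final_model.n_res)
                            if traj.final_model.has_coords(i)]])

    def test_same_seed_bitwise_identical(self, benchmark):
        case = benchmark["gap"]
        cfg = fast_config("2011", n_cycles=10)
        t1 = run_rebuild(case.template, case.alignment, case.library,
                         case.observed, cfg)
        t2 = run_rebuild(case.template, case.alignment, case.library,
                         case.observed, cfg)
        assert np.array_equal(t1.final_model.coords, t2.final_model.coords)
        assert t1.records == t2.records

    def test_different_seeds_differ(self, benchmark):
        case = benchmark["gap"]
        cfgs = [fast_config("2011", n_cycles=10, rng_seed=s) for s in (1, 2)]
        outs = [run_rebuild(case.template, case.alignment, case.library,
                            case.observed, c) for c in cfgs]
        assert not np.array_equal(outs[0].final_model.coords,
                                  outs[1].final_model.coords)

    def test_2011_freezes_aligned_residues_outside_flank(self, benchmark):
        from densloop.rebuild import _full_chain
        case = benchmark["gap"]
        cfg = fast_config("2011", n_cycles=10)
        start = _full_chain(thread_template(case.template, case.alignment),
                            case.alignment.target_sequence)
        traj = run_rebuild(case.template, case.alignment, case.library,
                           case.observed, cfg)
        frozen = ~traj.final_model.movable
        assert frozen.any()
        assert np.array_equal(traj.final_model.coords[frozen],
                              start.coords[frozen])

    def test_segment_independence_2011(self, benchmark):
        """Disabling a later gap segment's proposals (via max_gap_len)
        leaves an earlier segment's sampled coordinates bitwise identical:
        each segment draws from its own RNG stream and only moves its own
        span.  The final relax is turned off since it legitimately couples
        segments through the shared objective."""
        from densloop.model import AlignmentSpec
        case = benchmark["gap"]
        truth = case.truth
        seq = "".join(truth.seq)
        gap_a = set(range(19, 25))   # 6 residues, rebuilt in both runs
        gap_b = set(range(40, 47))   # 7 residues, disabled in the second run
        pairs = [(i, i) for i in range(1, truth.n_res + 1)
                 if i not in gap_a | gap_b]
        aln = AlignmentSpec(seq, seq, pairs)
        out = {}
        for tag, max_gap in (("both", 8), ("a_only", 6)):
            cfg = fast_config("2011", n_cycles=8, final_min_evals=0,
                              max_gap_len=max_gap)
            out[tag] = run_rebuild(truth, aln, case.library, case.observed,
                                   cfg).final_model
        span = slice(15, 28)  # gap A plus its movable flanks
        assert np.array_equal(out["both"].coords[span],
                              out["a_only"].coords[span])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            RebuildConfig(flank=1)
        with pytest.raises(ValueError):
            RebuildConfig(protocol="2020")
        with pytest.raises(ValueError):
            RebuildConfig(max_gap_len=0)


class TestFacade:
    def test_fit_returns_results_with_summary(self, benchmark):
        case = benchmark["gap"]
        rebuilder = LoopRebuilder(case.template, case.alignment,
                                  case.observed, case.library,
                                  config=fast_config("2011", n_cycles=8))
        res = rebuilder.fit(seed=5)
        text = res.summary()
        assert "protocol            2011" in text
        assert "seed                5" in text
        assert 0.0 <= res.acceptance_rate <= 1.0
        df = res.records_frame()
        assert {"cycle", "accepted", "score"} <= set(df.columns)

    def test_plot_trajectory_returns_axis(self, benchmark):
        import matplotlib
        matplotlib.use("Agg")
        case = benchmark["gap"]
        rebuilder = LoopRebuilder(case.template, case.alignment,
                                  case.observed, case.library,
                                  config=fast_config("2011", n_cycles=5))
        ax = rebuilder.fit(seed=0).plot_trajectory()
        assert ax.get_xlabel() == "proposal"
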