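"""Monte Carlo rebuild driver: both rebuilding protocols end to end.

The driver threads a template over a target sequence, then rebuilds every
unaligned (gap) segment of eight residues or fewer by fragment-based
Metropolis Monte Carlo, scored against the smooth low-resolution energy plus
the density term:

* protocol "2011" — classic torsion-space insertion: fragment torsions are
  written into the window, movement propagates to a cutpoint at the segment
  midpoint, the chain is re-closed geometrically by CCD, and residues
  aligned to the template (outside 2-5 flanking residues) never move.

* protocol "2013" — superposition insertion: fragment coordinates are built
  from the fragment torsions, rigidly superposed onto the current backbone
  over the window's flanking overlap residues, spliced in, and the whole
  structure is relaxed by Cartesian minimization (heal), letting the
  template backbone drift to accommodate the insertion and the density.

A statsmodels-style front end (:class:`LoopRebuilder` /
:class:`RebuildResults`) wraps the functional driver for interactive use.
"""

from __future__ import annotations

import dataclasses
import logging
import math

import numpy as np

from . import constants as const
from . import geometry as geom
from .closure import ccd_close
from .density import (DensityMap, SplineScoreField, build_spline_field,
                      fast_density_score, masked_residue_cc)
from .energy import EnergyModel
from .fragments import (DEFAULT_N_PICKS, FragmentLibrary, SubstitutionMatrix,
                        pick_fragments)
from .minimize import cartesian_minimize, heal_insertion
from .model import (TAG_ALIGNED, TAG_GAP_FLANK, TAG_REBUILT, AlignmentSpec,
                    BackboneModel)

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RebuildConfig:
    protocol: str = "2013"          # "2011" or "2013"
    n_cycles: int = 200             # Monte Carlo cycles per gap segment
    temperature: float = 2.0        # energy units
    cool_rate: float = 0.95         # geometric cooling factor
    cool_every: int = 20            # cycles between cooling steps
    flank: int = 3                  # movable residues adjacent to each gap (2-5)
    max_gap_len: int = 8            # longest gap segment that is rebuilt
    fast_density: bool = True       # fast spline score vs masked residue CC
    n_picks: int = DEFAULT_N_PICKS
    heal_evals: int = 250           # minimization budget per 2013 insertion
    final_min_evals: int = 400      # budget for the final relax
    rng_seed: int = 0

    def __post_init__(self):
        if not 2 <= self.flank <= 5:
            raise ValueError("flank must be in [2, 5]")
        if self.max_gap_len < 1:
            raise ValueError("max_gap_len must be >= 1")
        if self.protocol not in ("2011", "2013"):
            raise ValueError("protocol must be '2011' or '2013'")


@dataclasses.dataclass
class TrajectoryResult:
    final_model: BackboneModel
    records: list            # per-cycle dicts
    acceptance_rate: float
    seed: int
    protocol: str
    warnings: list = dataclasses.field(default_factory=list)


def metropolis_accept(delta: float, temperature: float, rng) -> bool:
    """Accept with probability min(1, exp(-delta/T))."""
    if delta <= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < math.exp(-delta / temperature))


# ---------------------------------------------------------------------------
# Threading
# ---------------------------------------------------------------------------

def thread_template(template: BackboneModel, alignment: AlignmentSpec,
                    target_seq: str | None = None) -> BackboneModel:
    """Map the template onto the target: aligned residues keep template
    coordinates but are renumbered to target numbering and mutated to the
    target identity; unaligned template residues are dropped."""
    if target_seq is None:
        target_seq = alignment.target_sequence
    resnum, seq, coords = [], [], []
    for t_num, q_num in alignment.aligned_pairs:
        if q_num < 1 or q_num > len(target_seq):
            raise ValueError(f"alignment references target residue {q_num} "
                             "outside the target sequence")
        try:
            ti = template.index_of(t_num)
        except KeyError:
            raise ValueError(f"alignment references template residue {t_num} "
                             "that has no coordinates") from None
        resnum.append(q_num)
        seq.append(target_seq[q_num - 1])
        coords.append(template.coords[ti])
    threaded = BackboneModel.from_arrays(resnum, seq, coords)
    threaded.tags[:] = TAG_ALIGNED
    return threaded


def _full_chain(threaded: BackboneModel, target_seq: str) -> BackboneModel:
    """Expand a threaded model to the full target chain, with NaN
    coordinates for gap residues."""
    n = len(target_seq)
    coords = np.full((n, 4, 3), np.nan)
    torsions = np.full((n, 3), np.nan)
    for i in range(threaded.n_res):
        q = threaded.resnum[i] - 1
        coords[q] = threaded.coords[i]
        torsions[q] = threaded.torsions[i]
    m = BackboneModel(
        resnum=np.arange(1, n + 1),
        seq=np.asarray(list(target_seq), dtype="<U1"),
        coords=coords,
        torsions=torsions,
        break_after=np.zeros(n, dtype=bool),
        movable=np.zeros(n, dtype=bool),
        tags=np.full(n, TAG_ALIGNED, dtype="<U9"),
    )
    m.detect_breaks()
    m.sync_torsions()
    return m


# ---------------------------------------------------------------------------
# Segment setup helpers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Segment:
    gs: int          # gap start, model index
    ge: int          # gap end, model index
    lo: int          # movable span start (incl. flanks)
    hi: int          # movable span end
    cut: int         # cutpoint index (break between cut and cut+1)
    windows: list    # window start indices
    picks: dict      # window start -> list of fragments


def _segment_setup(model: BackboneModel, gap: tuple[int, int, int],
                   library: FragmentLibrary, config: RebuildConfig,
                   matrix: SubstitutionMatrix) -> _Segment:
    gs, ge = gap[0] - 1, gap[1] - 1  # model indices
    length = ge - gs + 1
    frag_len = 3 if length <= 4 and library.of_length(3) else 9
    if not library.of_length(frag_len):
        frag_len = next(iter(sorted(library.fragments)))
    lo = max(gs - config.flank, 1)
    hi = min(ge + config.flank, model.n_res - 2)
    cut = (gs + ge) // 2
    windows = [w for w in range(lo, hi - frag_len + 2)
               if w + frag_len - 1 >= gs and w <= ge]
    windows = [w for w in windows if w + frag_len - 1 <= hi]
    picks = {}
    seq = "".join(model.seq)
    for w in windows:
        picks[w] = pick_fragments(seq[w:w + frag_len], library,
                                  config.n_picks, matrix)
    return _Segment(gs, ge, lo, hi, cut, windows, picks)


def _init_gap(model: BackboneModel, seg: _Segment) -> None:
    """Give gap residues starting coordinates: extended growth from both
    anchors toward the cutpoint, then CCD closure."""
    for i in range(seg.gs, seg.ge + 1):
        if not np.isfinite(model.torsions[i]).all():
            model.torsions[i] = (*const.EXTENDED_PHI_PSI, 180.0)
    model.rebuild_from_torsions(seg.lo - 1, "n_to_c", stop=seg.cut)
    model.rebuild_from_torsions(seg.hi + 1, "c_to_n", stop=seg.cut + 1)
    model.break_after[seg.cut] = True
    model.sync_torsions()
    ccd_close(model, (seg.lo, seg.hi), seg.cut)


def _mark_tags(model: BackboneModel, seg: _Segment) -> None:
    model.tags[seg.lo:seg.hi + 1] = TAG_GAP_FLANK
    model.tags[seg.gs:seg.ge + 1] = TAG_REBUILT
    model.movable[seg.lo:seg.hi + 1] = True


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def _mc_score(model: BackboneModel, energy: EnergyModel,
              field: SplineScoreField | None, observed: DensityMap | None,
              fast: bool) -> float:
    """Monte Carlo objective: low-resolution terms plus the density term via
    either the fast spline score or the masked residue correlation."""
    w_dens = energy.weights.get("density", 0.0)
    if fast or observed is None:
        e, _ = energy.total_energy(model, field)
        return float(e)
    low = EnergyModel({**energy.weights, "density": 0.0},
                      vdw_scale=energy.vdw_scale)
    e, _ = low.total_energy(model)
    _, total_cc = masked_residue_cc(model, observed)
    # scale the masked score so the density weight is comparable across the
    # two routes: total_cc is a negative mean correlation in [-1, 0]
    return float(e + w_dens * 100.0 * total_cc)


# ---------------------------------------------------------------------------
# Protocol 2011: torsion insertion + CCD closure
# ---------------------------------------------------------------------------

def rebuild_segment_2011(model: BackboneModel, seg: _Segment,
                         energy: EnergyModel, field: SplineScoreField | None,
                         observed: DensityMap | None, config: RebuildConfig,
                         rng, records: list | None = None) -> BackboneModel:
    current = model
    cur_score = _mc_score(current, energy, field, observed, config.fast_density)
    best, best_score = current, cur_score
    temperature = config.temperature
    n_closed = 0
    for cycle in range(config.n_cycles):
        if cycle and cycle % config.cool_every == 0:
            temperature *= config.cool_rate
        w = seg.windows[int(rng.integers(len(seg.windows)))]
        frag = seg.picks[w][int(rng.integers(len(seg.picks[w])))]
        prop = current.copy()
        prop.torsions[w:w + frag.length] = frag.torsion_array()
        prop.rebuild_from_torsions(seg.lo - 1, "n_to_c", stop=seg.cut)
        prop.rebuild_from_torsions(seg.hi + 1, "c_to_n", stop=seg.cut + 1)
        prop.break_after[seg.cut] = True
        prop.sync_torsions()
        _, rep = ccd_close(prop, (seg.lo, seg.hi), seg.cut)
        if not rep.closed:
            if records is not None:
                records.append(dict(cycle=cycle, segment=seg.gs + 1,
                                    accepted=False, closed=False,
                                    score=cur_score))
            continue
        n_closed += 1
        score = _mc_score(prop, energy, field, observed, config.fast_density)
        accepted = metropolis_accept(score - cur_score, temperature, rng)
        if accepted:
            current, cur_score = prop, score
            if score < best_score:
                best, best_score = prop, score
        if records is not None:
            records.append(dict(cycle=cycle, segment=seg.gs + 1,
                                accepted=accepted, closed=True, score=score))
    if n_closed == 0:
        best = best.copy()
        best.strained = True
        logger.warning("segment %d-%d: no closable proposal in any cycle",
                       seg.gs + 1, seg.ge + 1)
    return best


# ---------------------------------------------------------------------------
# Protocol 2013: superposition insertion + whole-structure healing
# ---------------------------------------------------------------------------

def _superpose_fragment(model: BackboneModel, frag, w: int,
                        flank: int) -> np.ndarray | None:
    """Build the fragment from its torsions and superpose it onto the
    current backbone over the window's end overlap residues.  Returns the
    transformed (L, 4, 3) window coordinates, or None if the overlap
    residues are unusable."""
    length = frag.length
    n_ov = min(flank, max(1, (length - 1) // 2))
    fm = BackboneModel.from_torsions(frag.source_sequence, frag.torsion_array())
    ov_idx = list(range(n_ov)) + list(range(length - n_ov, length))
    tgt = model.coords[[w + i for i in ov_idx]][:, :3].reshape(-1, 3)
    mob = fm.coords[ov_idx][:, :3].reshape(-1, 3)
    if not np.isfinite(tgt).all():
        return None
    r_mat, t, _ = geom.kabsch(mob, tgt)
    return fm.coords @ r_mat.T + t


def rebuild_segment_2013(model: BackboneModel, seg: _Segment,
                         energy: EnergyModel, field: SplineScoreField | None,
                         observed: DensityMap | None, config: RebuildConfig,
                         rng, records: list | None = None) -> BackboneModel:
    current = model
    cur_score = _mc_score(current, energy, field, observed, config.fast_density)
    best, best_score = current, cur_score
    temperature = config.temperature
    for cycle in range(config.n_cycles):
        if cycle and cycle % config.cool_every == 0:
            temperature *= config.cool_rate
        w = seg.windows[int(rng.integers(len(seg.windows)))]
        frag = seg.picks[w][int(rng.integers(len(seg.picks[w])))]
        new_window = _superpose_fragment(current, frag, w, config.flank)
        if new_window is None:
            logger.info("cycle %d: overlap residues missing, proposal skipped",
                        cycle)
            continue
        prop = current.copy()
        prop.coords[w:w + frag.length] = new_window
        prop.break_after[:] = False
        prop.detect_breaks()
        prop.sync_torsions()
        prop = heal_insertion(prop, (w, w + frag.length - 1), energy, field,
                              max_evals=config.heal_evals)
        score = _mc_score(prop, energy, field, observed, config.fast_density)
        accepted = metropolis_accept(score - cur_score, temperature, rng)
        if accepted:
            current, cur_score = prop, score
            if score < best_score:
                best, best_score = prop, score
        if records is not None:
            records.append(dict(cycle=cycle, segment=seg.gs + 1,
                                accepted=accepted, closed=True, score=score))
    return best


# ---------------------------------------------------------------------------
# Full driver
# ---------------------------------------------------------------------------

def run_rebuild(template: BackboneModel, alignment: AlignmentSpec,
                library: FragmentLibrary, observed: DensityMap,
                config: RebuildConfig | None = None,
                energy: EnergyModel | None = None) -> TrajectoryResult:
    """Thread, rebuild every short gap segment, final relax.

    Gap segments longer than ``config.max_gap_len`` (and segments touching a
    chain terminus) are left as recorded chain breaks with a warning.  The
    trajectory is fully determined by ``config.rng_seed``.
    """
    config = config or RebuildConfig()
    energy = energy or EnergyModel()
    matrix = SubstitutionMatrix.blosum62()
    obs = observed.standardized()
    field = build_spline_field(obs)
    threaded = thread_template(template, alignment)
    model = _full_chain(threaded, alignment.target_sequence)
    records: list = []
    warns: list = []
    protocol_fn = (rebuild_segment_2011 if config.protocol == "2011"
                   else rebuild_segment_2013)
    gaps = sorted(alignment.gap_segments)
    for gap in gaps:
        qs, qe, length = gap
        if length > config.max_gap_len:
            warns.append(f"gap {qs}-{qe} ({length} residues) exceeds "
                         f"max_gap_len={config.max_gap_len}; left broken")
            logger.warning(warns[-1])
            continue
        if qs <= 1 or qe >= model.n_res:
            warns.append(f"terminal gap {qs}-{qe} not rebuilt")
            logger.warning(warns[-1])
            continue
        seg = _segment_setup(model, gap, library, config, matrix)
        if not seg.windows:
            warns.append(f"gap {qs}-{qe}: no usable fragment windows")
            logger.warning(warns[-1])
            continue
        _mark_tags(model, seg)
        _init_gap(model, seg)
        # each segment is sampled independently with its own child stream
        rng = np.random.default_rng([config.rng_seed, qs])
        model = protocol_fn(model, seg, energy, field, obs, config, rng,
                            records)
    if not gaps:
        logger.info("no gap segments: degenerate run, final minimize only")
    # final relax: whole structure for 2013; movable residues only for 2011
    if config.protocol == "2013":
        movable = np.array([model.has_coords(i) for i in range(model.n_res)])
    else:
        movable = model.movable.copy()
    if movable.any() and config.final_min_evals > 0:
        model, _ = cartesian_minimize(model, energy, field, movable=movable,
                                      max_evals=config.final_min_evals)
    n_prop = sum(1 for r in records)
    n_acc = sum(1 for r in records if r["accepted"])
    rate = n_acc / n_prop if n_prop else 0.0
    return TrajectoryResult(final_model=model, records=records,
                            acceptance_rate=rate, seed=config.rng_seed,
                            protocol=config.protocol, warnings=warns)


# ---------------------------------------------------------------------------
# statsmodels-style front end
# ---------------------------------------------------------------------------

class LoopRebuilder:
    """Density-guided loop rebuilding model.

    Bundles the inputs of a rebuild problem — template structure, alignment
    to the target sequence, observed density map and fragment library — with
    a :class:`RebuildConfig`; :meth:`fit` runs one Monte Carlo trajectory
    and returns a :class:`RebuildResults`.

    Examples
    --------
    >>> rebuilder = LoopRebuilder(template, alignment, density_map, library,
    ...                           config=RebuildConfig(protocol="2013"))
    >>> results = rebuilder.fit(seed=7)
    >>> print(results.summary())
    """

    def __init__(self, template: BackboneModel, alignment: AlignmentSpec,
                 observed: DensityMap, library: FragmentLibrary,
                 config: RebuildConfig | None = None,
                 energy: EnergyModel | None = None):
        self.template = template
        self.alignment = alignment
        self.observed = observed
        self.library = library
        self.config = config or RebuildConfig()
        self.energy = energy or EnergyModel()

    @classmethod
    def from_files(cls, template_pdb, alignment_file, map_file, library_file,
                   **kwargs) -> "LoopRebuilder":
        from . import io as dio
        from .fragments import read_library
        return cls(dio.read_pdb(template_pdb),
                   dio.read_alignment(alignment_file),
                   dio.read_map(map_file),
                   read_library(library_file), **kwargs)

    def fit(self, seed: int | None = None) -> "RebuildResults":
        config = dataclasses.replace(
            self.config,
            rng_seed=self.config.rng_seed if seed is None else int(seed))
        traj = run_rebuild(self.template, self.alignment, self.library,
                           self.observed, config, self.energy)
        return RebuildResults(self, traj, config)

    def sample(self, n_models: int, seed: int = 0) -> list:
        """Generate an ensemble of independently seeded trajectories."""
        return [self.fit(seed=seed + i) for i in range(n_models)]


class RebuildResults:
    """Results of one rebuild trajectory: the final model, the per-cycle
    Monte Carlo record, and scoring diagnostics."""

    def __init__(self, rebuilder: LoopRebuilder, trajectory: TrajectoryResult,
                 config: RebuildConfig):
        self.rebuilder = rebuilder
        self.trajectory = trajectory
        self.config = config
        self.model = trajectory.final_model

    @property
    def acceptance_rate(self) -> float:
        return self.trajectory.acceptance_rate

    def records_frame(self):
        import pandas as pd
        return pd.DataFrame(self.trajectory.records)

    def density_score(self) -> float:
        obs = self.rebuilder.observed.standardized()
        field = build_spline_field(obs)
        score, _ = fast_density_score(self.model, field)
        return score

    def summary(self) -> str:
        t = self.trajectory
        n_prop = len(t.records)
        lines = [
            "Loop rebuild results",
            "=" * 44,
            f"protocol            {t.protocol}",
            f"seed                {t.seed}",
            f"residues            {self.model.n_res}",
            f"gap segments        {len(self.rebuilder.alignment.gap_segments)}",
            f"proposals           {n_prop}",
            f"acceptance rate     {t.acceptance_rate:.3f}",
            f"fast density score  {self.density_score():.2f}",
            f"strained            {self.model.strained}",
        ]
        for w in t.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def plot_trajectory(self, ax=None):
        """Score trace over Monte Carlo cycles (accepted moves marked)."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 3.5))
        df = self.records_frame()
        if len(df):
            ax.plot(range(len(df)), df["score"], lw=0.8, color="0.4")
            acc = df[df["accepted"]]
            ax.plot(acc.index, acc["score"], ".", ms=4, color="tab:red",
                    label="accepted")
            ax.legend(frameon=False)
        ax.set_xlabel("proposal")
        ax.set_ylabel("MC score")
        ax.set_title(f"protocol {self.trajectory.protocol}, "
                     f"seed {self.trajectory.seed}")
        return ax

    def write_pdb(self, path) -> None:
        from . import io as dio
        dio.write_pdb(self.model, path)
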