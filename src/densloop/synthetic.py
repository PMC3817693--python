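"""Synthetic fixture generator.

Produces the ingredients of a desk-scale rebuilding benchmark: a
ground-truth structure with designed secondary-structure topology, a
corrupted template (displaced loop, register-shifted alignment, or deleted
segment), a noisy model-biased density map with a controllable truth-map
correlation, and a fragment library mixing near-native fragments with
decoys.  The three packaged cases mirror the classic failure modes of
template-frozen rebuilding: a clean loop gap, an alignment register shift
inside a beta-hairpin, and a template loop displaced away from the truth.

All generation is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
import re

import numpy as np

from . import constants as const
from .density import DensityMap, simulate_on_grid
from .energy import EnergyModel
from .evaluate import model_map_cc
from .fragments import Fragment, FragmentLibrary, build_library
from .minimize import cartesian_minimize
from .model import AlignmentSpec, BackboneModel
from .rebuild import thread_template  # noqa: F401  (re-exported convenience)

# 2-residue turn used for the 'T' topology element; with the backbone
# H-bond and repulsion terms this folds an E-T-E stretch into a paired
# antiparallel hairpin after relaxation.
TURN_PHI_PSI = ((55.0, 47.0), (78.0, 6.0))
COIL_BASINS = ((-60.0, -30.0), (-90.0, 0.0), (-140.0, 70.0),
               (-75.0, 150.0), (60.0, 30.0))

_ELEMENT_RE = re.compile(r"([HELT])(\d+)")


@dataclasses.dataclass
class BenchmarkCase:
    name: str
    truth: BackboneModel
    template: BackboneModel
    alignment: AlignmentSpec
    observed: DensityMap       # noisy, model-biased guidance map
    selection_map: DensityMap  # held-out map for model selection
    library: FragmentLibrary
    input_cc: float            # CC(truth, observed) actually achieved
    meta: dict = dataclasses.field(default_factory=dict)


def _parse_spec(spec: str) -> list[tuple[str, int]]:
    elements = []
    for part in spec.split("-"):
        m = _ELEMENT_RE.fullmatch(part.strip())
        if not m:
            raise ValueError(f"bad topology element {part!r} "
                             "(expected H<len>, E<len>, L<len> or T<len>)")
        elements.append((m.group(1), int(m.group(2))))
    if not elements:
        raise ValueError("empty topology spec")
    return elements


def _random_sequence(n: int, rng) -> str:
    return "".join(rng.choice(list(const.AA1), size=n))


def make_topology(spec: str, rng, torsion_noise: float = 3.0,
                  relax: bool = True, max_attempts: int = 1000,
                  sequence: str | None = None) -> BackboneModel:
    """Build a clash-free chain from a secondary-structure string such as
    ``"H12-L6-E8-T2-E8"``.

    Helix/strand elements get basin-typical torsions plus Gaussian noise
    (sigma ``torsion_noise`` degrees); loops draw per-residue coil torsions
    and are resampled until the soft-sphere repulsion is zero.  With
    ``relax=True`` the built chain is then relaxed under the no-density
    energy so designed hairpins actually pair.
    """
    rng = np.random.default_rng(rng)
    elements = _parse_spec(spec)
    n = sum(length for _, length in elements)
    if sequence is None:
        sequence = _random_sequence(n, rng)
    if len(sequence) != n:
        raise ValueError("sequence length does not match topology")
    kinds = np.concatenate([[kind] * length for kind, length in elements])
    loop_pos = np.nonzero(kinds == "L")[0]
    base = np.empty((n, 3))
    turn_counter = 0
    for i, kind in enumerate(kinds):
        if kind == "H":
            base[i, :2] = const.HELIX_PHI_PSI
        elif kind == "E":
            base[i, :2] = const.STRAND_PHI_PSI
        elif kind == "T":
            base[i, :2] = TURN_PHI_PSI[turn_counter % len(TURN_PHI_PSI)]
            turn_counter += 1
        else:
            base[i, :2] = (np.nan, np.nan)  # loop: drawn per attempt
        base[i, 2] = 180.0
    for attempt in range(max_attempts):
        tors = base.copy()
        for i in loop_pos:
            tors[i, :2] = COIL_BASINS[int(rng.integers(len(COIL_BASINS)))]
        tors[:, :2] += rng.normal(0.0, torsion_noise, (n, 2))
        tors[:, 2] += rng.normal(0.0, min(torsion_noise, 2.0), n)
        model = BackboneModel.from_torsions(sequence, tors)
        if _loop_clash_free(model, kinds):
            break
    else:
        raise ValueError(f"no clash-free build of {spec!r} in "
                         f"{max_attempts} attempts")
    if relax:
        relax_energy = EnergyModel({"density": 0})
        model, _ = cartesian_minimize(model, relax_energy, max_evals=800)
    return model


def _loop_clash_free(model: BackboneModel, kinds: np.ndarray) -> bool:
    """True when no soft-sphere clash involves a loop residue (designed
    turns carry a little pre-relaxation strain that minimization removes,
    so only the randomly drawn loop torsions are gated)."""
    from scipy.spatial import cKDTree

    from .density import _model_atoms
    pos, types, res = _model_atoms(model)
    radii = np.array([const.VDW_RADII[t] for t in const.ATOM_TYPES])
    tree = cKDTree(pos)
    pairs = tree.query_pairs(2.0 * radii.max(), output_type="ndarray")
    if len(pairs) == 0:
        return True
    i, j = pairs[:, 0], pairs[:, 1]
    keep = np.abs(res[i] - res[j]) >= const.VDW_MIN_SEQ_SEP
    i, j = i[keep], j[keep]
    d = np.linalg.norm(pos[i] - pos[j], axis=1)
    clash = d < radii[types[i]] + radii[types[j]]
    loopy = (kinds[res[i]] == "L") | (kinds[res[j]] == "L")
    return not np.any(clash & loopy)


def make_template(truth: BackboneModel,
                  loop_shift: tuple[int, int, float] | None = None,
                  register_shift: tuple[int, int] | None = None,
                  delete_segment: tuple[int, int] | None = None,
                  rng=None):
    """Corrupt a ground-truth structure into a (template, alignment) pair.

    loop_shift : (start, end, distance) — rigidly displace the loop's
        residues (1-based, inclusive) by ``distance`` A in a random
        direction.
    register_shift : (insert_at, k) — the alignment inserts k unaligned
        target residues at ``insert_at`` and maps every later target
        residue to the template residue k earlier: the classic
        insertion-in-a-strand misalignment.
    delete_segment : (start, end) — remove the residues from the template,
        creating a gap segment.
    """
    rng = np.random.default_rng(rng)
    n = truth.n_res
    seq = "".join(truth.seq)
    coords = truth.coords.copy()
    if loop_shift is not None:
        s, e, dist = loop_shift
        if not (1 <= s <= e <= n):
            raise ValueError("loop_shift segment outside the chain")
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        coords[s - 1:e] += dist * direction
    keep = np.ones(n, dtype=bool)
    if delete_segment is not None:
        s, e = delete_segment
        if not (1 <= s <= e <= n):
            raise ValueError("delete_segment outside the chain")
        keep[s - 1:e] = False
    kept = np.nonzero(keep)[0]
    template = BackboneModel(
        resnum=np.arange(1, len(kept) + 1),
        seq=truth.seq[kept].copy(),
        coords=coords[kept],
        torsions=np.full((len(kept), 3), np.nan),
        break_after=np.zeros(len(kept), dtype=bool),
        movable=np.ones(len(kept), dtype=bool),
        tags=np.full(len(kept), "aligned", dtype="<U9"),
    )
    template.detect_breaks()
    template.sync_torsions()
    if register_shift is not None:
        if delete_segment is not None:
            raise ValueError("register_shift cannot combine with delete_segment")
        m, k = register_shift
        if not (2 <= m and m + k <= n):
            raise ValueError(f"register shift of {k} at {m} is larger than "
                             "the chain supports")
        pairs = [(i, i) for i in range(1, m)]
        pairs += [(i - k, i) for i in range(m + k, n + 1)]
    else:
        # identity over kept residues, in template numbering
        new_num = np.cumsum(keep)
        pairs = [(int(new_num[q]), q + 1) for q in kept]
    alignment = AlignmentSpec(template_sequence="".join(template.seq),
                              target_sequence=seq, aligned_pairs=pairs)
    return template, alignment


def make_noisy_map(truth: BackboneModel, template: BackboneModel | None,
                   resolution: float, bias_fraction: float = 0.3,
                   target_cc: float | None = None, rng=None,
                   spacing: float | None = None,
                   padding: float = 6.0) -> DensityMap:
    """Noisy model-biased map: a (1-b) truth + b template density blend plus
    Gaussian voxel noise, standardized to zero mean and unit SD.

    With ``target_cc`` given, the noise level is bisected until
    ``model_map_cc(truth, map)`` lands within +/-0.02 of the target.
    """
    if not 0.0 <= bias_fraction <= 1.0:
        raise ValueError("bias_fraction must be in [0, 1]")
    rng = np.random.default_rng(rng)
    spacing = resolution / 3.0 if spacing is None else spacing
    pts = [truth.backbone_atoms()]
    if template is not None:
        pts.append(template.backbone_atoms())
    allpts = np.vstack(pts)
    lo = allpts.min(axis=0) - padding
    hi = allpts.max(axis=0) + padding
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    grid = DensityMap(np.zeros(tuple(shape)), np.full(3, spacing), lo, resolution)
    sim_t = simulate_on_grid(truth, grid).values
    if bias_fraction > 0.0 and template is not None:
        sim_b = simulate_on_grid(template, grid).values
    else:
        sim_b = np.zeros_like(sim_t)
    base = (1.0 - bias_fraction) * sim_t + bias_fraction * sim_b
    noise = rng.standard_normal(base.shape)
    scale = base.std()

    def assemble(sigma: float) -> DensityMap:
        return DensityMap(base + sigma * scale * noise, grid.spacing,
                          grid.origin, resolution).standardized()

    if target_cc is None:
        return assemble(0.0)
    cc_max = model_map_cc(truth, assemble(0.0), resolution)
    if target_cc > cc_max + 0.02:
        raise ValueError(f"target_cc {target_cc} unreachable: achievable "
                         f"range is (0, {cc_max:.3f}] with "
                         f"bias_fraction={bias_fraction}")
    s_lo, s_hi = 0.0, 1.0
    while model_map_cc(truth, assemble(s_hi), resolution) > target_cc:
        s_lo, s_hi = s_hi, s_hi * 2.0
        if s_hi > 1e4:
            raise ValueError("noise bisection failed to bracket target_cc")
    for _ in range(40):
        mid = 0.5 * (s_lo + s_hi)
        cc = model_map_cc(truth, assemble(mid), resolution)
        if abs(cc - target_cc) <= 0.02:
            return assemble(mid)
        if cc > target_cc:
            s_lo = mid
        else:
            s_hi = mid
    raise ValueError("noise bisection did not converge")


# ---------------------------------------------------------------------------
# Packaged benchmark cases
# ---------------------------------------------------------------------------

_CASE_TOPOLOGY = {
    "gap": "H16-L8-H16-L4-E7-T2-E7",
    "register": "H14-L4-E8-T2-E8-L4-H14",
    "loop": "H14-L10-H14-L4-E7-T2-E7",
}
DEFAULT_RESOLUTION = 3.0
DEFAULT_TARGET_CC = 0.40
DEFAULT_BIAS = 0.3
_NATIVE_NOISE = 5.0  # deg, torsion noise on near-native library fragments


def _native_fragments(truth: BackboneModel, gap: tuple[int, int], length: int,
                      flank: int, rng, n_variants: int = 5) -> list[Fragment]:
    gs, ge = gap[0] - 1, gap[1] - 1
    lo = max(gs - flank, 1)
    hi = min(ge + flank, truth.n_res - 2)
    frags = []
    fill = np.array([*const.EXTENDED_PHI_PSI, 180.0])
    tors_all = np.where(np.isfinite(truth.torsions), truth.torsions, fill)
    for w in range(lo, hi - length + 2):
        if w + length - 1 < gs or w > ge:
            continue
        native = tors_all[w:w + length]
        seq = "".join(truth.seq[w:w + length])
        for v in range(n_variants):
            noise = rng.normal(0.0, _NATIVE_NOISE, native.shape) if v else 0.0
            frags.append(Fragment(
                length=length,
                torsions=tuple(map(tuple, native + noise)),
                source_sequence=seq,
                source_id=f"native_w{w:03d}_v{v}",
                window_start=w,
            ))
    return frags


def _case_library(truth: BackboneModel, gaps, rng, flank: int = 5) -> FragmentLibrary:
    decoys = [make_topology("H10-L5-E8-L4-H12-L6-E8", rng, relax=False),
              make_topology("E6-L4-H14-L5-E6-L5-H10", rng, relax=False)]
    lib = FragmentLibrary({}, metadata="synthetic benchmark library")
    for length in (3, 9):
        dec = build_library(decoys, length)
        for f in dec.of_length(length):
            lib.add(f)
        for gap in gaps:
            for f in _native_fragments(truth, gap, length, flank, rng):
                lib.add(f)
    return lib


def _verify_native_coverage(lib: FragmentLibrary, truth: BackboneModel,
                            gaps) -> None:
    from .model import torsion_rmsd
    fill = np.array([*const.EXTENDED_PHI_PSI, 180.0])
    tors_all = np.where(np.isfinite(truth.torsions), truth.torsions, fill)
    for gap in gaps:
        gs = gap[0] - 1
        for length in (3, 9):
            best = np.inf
            for f in lib.of_length(length):
                w = f.window_start
                if not f.source_id.startswith("native"):
                    continue
                if w + length - 1 < gs or w > gap[1] - 1:
                    continue
                dev = torsion_rmsd(f.torsion_array(), tors_all[w:w + length])
                best = min(best, dev)
            if not best < 10.0:
                raise AssertionError(
                    f"no near-native {length}-mer for gap {gap}: best {best}")


def make_benchmark(seed: int = 0, out_dir: str | None = None,
                   cases=("gap", "register", "loop"),
                   resolution: float = DEFAULT_RESOLUTION,
                   target_cc: float = DEFAULT_TARGET_CC,
                   bias_fraction: float = DEFAULT_BIAS) -> dict:
    """Generate the packaged three-case benchmark (deterministic in seed).

    Cases: ``gap`` — clean 6-residue loop deletion; ``register`` — +2
    register shift placing an insertion inside a beta-hairpin strand;
    ``loop`` — template loop displaced 4 A with a 4-residue deletion at its
    centre.  Optionally writes each case to ``out_dir/<name>/``.
    """
    out: dict[str, BenchmarkCase] = {}
    for name in cases:
        rng = np.random.default_rng([seed, list(_CASE_TOPOLOGY).index(name)])
        truth = make_topology(_CASE_TOPOLOGY[name], rng)
        meta: dict = {"topology": _CASE_TOPOLOGY[name], "seed": seed}
        if name == "gap":
            template, alignment = make_template(truth,
                                                delete_segment=(19, 24))
            meta["perturbation"] = "delete 19-24"
        elif name == "register":
            template, alignment = make_template(truth,
                                                register_shift=(32, 2))
            meta["perturbation"] = "register shift +2 at 32"
        else:
            # displaced loop: residues 15-20 sit 4 A from the truth and are
            # aligned (so the 2011 protocol freezes them in the wrong
            # place); the adjacent 5-residue gap is what gets rebuilt
            template, alignment = make_template(
                truth, loop_shift=(15, 20, 4.0), delete_segment=(21, 25),
                rng=rng)
            meta["perturbation"] = "loop 15-20 shifted 4 A; delete 21-25"
        observed = make_noisy_map(truth, template, resolution, bias_fraction,
                                  target_cc, rng)
        selection = make_noisy_map(truth, template, resolution + 0.5,
                                   bias_fraction, target_cc, rng)
        library = _case_library(truth, alignment.gap_segments, rng)
        _verify_native_coverage(library, truth, alignment.gap_segments)
        cc_in = model_map_cc(truth, observed, resolution)
        case = BenchmarkCase(name, truth, template, alignment, observed,
                             selection, library, cc_in, meta)
        out[name] = case
        if out_dir is not None:
            _write_case(case, os.path.join(out_dir, name))
    return out


def _write_case(case: BenchmarkCase, case_dir: str) -> None:
    from . import io as dio
    from .fragments import write_library
    os.makedirs(case_dir, exist_ok=True)
    dio.write_pdb(case.truth, os.path.join(case_dir, "truth.pdb"))
    dio.write_pdb(case.template, os.path.join(case_dir, "template.pdb"))
    dio.write_alignment(case.alignment, os.path.join(case_dir, "align.aln"))
    dio.write_map(case.observed, os.path.join(case_dir, "map.mrc"))
    dio.write_map(case.selection_map, os.path.join(case_dir, "selmap.mrc"))
    write_library(case.library, os.path.join(case_dir, "frags.lib"))
    manifest = {"name": case.name, "input_cc": round(case.input_cc, 4),
                **case.meta}
    with open(os.path.join(case_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
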