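"""File I/O: PDB models, CCP4/MRC density maps, FASTA and gapped alignments.

Parsing and writing of the standard formats is delegated to gemmi; this
module adapts between gemmi's objects and the package's backbone-level
containers.  Restrictions: single chain per model (first chain by default),
orthogonal unit cells only (maps are treated as P1 boxes), mode-2 maps.
"""

from __future__ import annotations

import logging
import os
import warnings

import gemmi
import numpy as np

from . import constants as k
from .density import DensityMap
from .model import BackboneModel, N, CA, C, O

logger = logging.getLogger(__name__)

_BACKBONE = {"N": N, "CA": CA, "C": C, "O": O}


def read_pdb(path, chain: str | None = None) -> BackboneModel:
    """Read backbone coordinates for one chain of a PDB file.

    Residues missing any of N/CA/C are dropped (leaving a recorded chain
    break); missing O atoms are rebuilt from ideal geometry.  Alternate
    conformations keep the first conformer; residues with insertion codes
    are skipped.  All cases are warned about.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0 or len(st[0]) == 0:
        raise ValueError(f"{path}: no chains found")
    ch = None
    if chain is None:
        ch = st[0][0]
    else:
        for cand in st[0]:
            if cand.name == chain:
                ch = cand
        if ch is None:
            raise ValueError(f"{path}: no chain named {chain!r}")
    resnum, seq, coords = [], [], []
    for res in ch:
        if res.het_flag == "H" and res.name not in k.AA_3TO1:
            continue
        if res.seqid.icode not in ("", " "):
            warnings.warn(f"{path}: skipping residue {res.seqid.num}{res.seqid.icode} "
                          "(insertion codes unsupported)")
            continue
        xyz = np.full((4, 3), np.nan)
        seen_alt = False
        for atom in res:
            if atom.name not in _BACKBONE:
                continue
            slot = _BACKBONE[atom.name]
            if np.isfinite(xyz[slot]).all():
                seen_alt = True
                continue  # keep the first conformer
            if atom.altloc not in ("", "\x00", "A"):
                seen_alt = True
                if atom.altloc != "A" and np.isfinite(xyz[slot]).all():
                    continue
            xyz[slot] = (atom.pos.x, atom.pos.y, atom.pos.z)
        if seen_alt:
            warnings.warn(f"{path}: residue {res.seqid.num} has alternate "
                          "conformers; first kept")
        if not np.isfinite(xyz[:3]).all():
            warnings.warn(f"{path}: residue {res.seqid.num} missing backbone "
                          "atoms; dropped (chain break recorded)")
            continue
        resnum.append(res.seqid.num)
        seq.append(k.AA_3TO1.get(res.name, "X"))
        coords.append(xyz)
    if not resnum:
        raise ValueError(f"{path}: no parseable residues")
    m = BackboneModel.from_arrays(resnum, seq, coords)
    missing_o = ~np.isfinite(m.coords[:, O]).all(axis=1)
    if missing_o.any():
        m._place_oxygen(0, m.n_res - 1)
    return m


def write_pdb(model: BackboneModel, path, write_cb: bool = True) -> None:
    """Write the backbone (plus a virtual CB for non-glycine residues)."""
    st = gemmi.Structure()
    st.name = "densloop"
    md = gemmi.Model("1")
    ch = gemmi.Chain("A")
    cb = model.virtual_cb()
    for i in range(model.n_res):
        if not model.has_coords(i):
            continue
        res = gemmi.Residue()
        res.name = k.AA_1TO3.get(str(model.seq[i]), "UNK")
        res.seqid = gemmi.SeqId(int(model.resnum[i]), " ")
        for slot, (name, elem) in enumerate(
                zip(("N", "CA", "C", "O"), ("N", "C", "C", "O"))):
            p = model.coords[i, slot]
            if not np.isfinite(p).all():
                continue
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(elem)
            atom.pos = gemmi.Position(*p)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        if write_cb and model.seq[i] != "G" and np.isfinite(cb[i]).all():
            atom = gemmi.Atom()
            atom.name = "CB"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*cb[i])
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        ch.add_residue(res)
    md.add_chain(ch)
    st.add_model(md)
    st.setup_entities()
    st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# CCP4/MRC maps
# ---------------------------------------------------------------------------

def read_map(path) -> DensityMap:
    """Read an orthogonal-cell mode-2 CCP4/MRC map."""
    _check_map_size(path)
    ccp4 = gemmi.read_ccp4_map(str(path))
    cell = ccp4.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError(f"{path}: non-orthogonal unit cell is unsupported")
    values = np.array(ccp4.grid, copy=True, dtype=float)
    shape = np.asarray(values.shape)
    spacing = np.array([cell.a, cell.b, cell.c]) / shape
    origin = np.array([ccp4.header_float(w) for w in (50, 51, 52)])
    resolution = ccp4.header_float(30)
    if not np.isfinite(resolution) or resolution <= 0:
        resolution = 3.0 * float(spacing.max())
    return DensityMap(values, spacing, origin, float(resolution))


def write_map(dmap: DensityMap, path) -> None:
    """Write a mode-2 CCP4/MRC map (P1, orthogonal cell); the origin is
    stored in the MRC-2000 ORIGIN header words and the nominal resolution in
    an unused header float."""
    ccp4 = gemmi.Ccp4Map()
    shape = dmap.shape
    grid = gemmi.FloatGrid(*shape)
    grid.set_unit_cell(gemmi.UnitCell(
        shape[0] * dmap.spacing[0], shape[1] * dmap.spacing[1],
        shape[2] * dmap.spacing[2], 90.0, 90.0, 90.0))
    grid.spacegroup = gemmi.SpaceGroup("P1")
    arr = np.array(grid, copy=False)
    arr[...] = dmap.values.astype(np.float32)
    ccp4.grid = grid
    ccp4.update_ccp4_header(2)
    for w, v in zip((50, 51, 52), dmap.origin):
        ccp4.set_header_float(w, float(v))
    ccp4.set_header_float(30, float(dmap.resolution))
    ccp4.write_ccp4_map(str(path))


def _check_map_size(path) -> None:
    size = os.path.getsize(path)
    if size < 1024:
        raise ValueError(f"{path}: truncated map file, header needs 1024 bytes "
                         f"({1024 - size} bytes missing)")
    with open(path, "rb") as fh:
        head = np.frombuffer(fh.read(1024), dtype="<i4")
    nx, ny, nz = (int(v) for v in head[:3])
    mode = int(head[3])
    nsymbt = int(head[23])
    bytes_per = {0: 1, 1: 2, 2: 4, 6: 2}.get(mode)
    if bytes_per is None:
        raise ValueError(f"{path}: unsupported map mode {mode}")
    expected = 1024 + nsymbt + nx * ny * nz * bytes_per
    if size < expected:
        raise ValueError(f"{path}: truncated map file ({expected - size} bytes "
                         f"missing of expected {expected})")


# ---------------------------------------------------------------------------
# FASTA / gapped alignment text
# ---------------------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    records: dict[str, str] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                records[name] = ""
            elif name is not None:
                records[name] += line
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_alignment(aln, path, template_name="template", target_name="target") -> None:
    """Write an AlignmentSpec as two aligned, gapped FASTA records."""
    rows = _alignment_rows(aln)
    with open(path, "w") as fh:
        fh.write(f">{template_name}\n{rows[0]}\n>{target_name}\n{rows[1]}\n")


def _alignment_rows(aln) -> tuple[str, str]:
    tmpl, targ = [], []
    ti, qi = 1, 1
    pairs = list(aln.aligned_pairs)
    while pairs or ti <= len(aln.template_sequence) or qi <= len(aln.target_sequence):
        if pairs and pairs[0] == (ti, qi):
            tmpl.append(aln.template_sequence[ti - 1])
            targ.append(aln.target_sequence[qi - 1])
            ti += 1
            qi += 1
            pairs.pop(0)
        elif pairs and ti < pairs[0][0] or (not pairs and ti <= len(aln.template_sequence)):
            tmpl.append(aln.template_sequence[ti - 1])
            targ.append("-")
            ti += 1
        elif qi <= len(aln.target_sequence):
            tmpl.append("-")
            targ.append(aln.target_sequence[qi - 1])
            qi += 1
        else:
            break
    return "".join(tmpl), "".join(targ)


def read_alignment(path):
    """Read a two-record gapped FASTA alignment (template first, target
    second) into an AlignmentSpec."""
    from .model import AlignmentSpec

    records = read_fasta(path)
    if len(records) != 2:
        raise ValueError(f"{path}: expected exactly two aligned records")
    (tname, trow), (qname, qrow) = records.items()
    if len(trow) != len(qrow):
        raise ValueError(f"{path}: aligned rows differ in length")
    pairs = []
    ti = qi = 0
    for a, b in zip(trow, qrow):
        if a != "-":
            ti += 1
        if b != "-":
            qi += 1
        if a != "-" and b != "-":
            pairs.append((ti, qi))
    return AlignmentSpec(
        template_sequence=trow.replace("-", ""),
        target_sequence=qrow.replace("-", ""),
        aligned_pairs=pairs,
    )
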