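"""Backbone structure representation.

A :class:`BackboneModel` stores one protein chain at backbone resolution
(N, CA, C, O per residue), together with the (phi, psi, omega) torsions, a
movability mask used by the rebuild protocols, per-residue provenance tags
and explicit chain-break bookkeeping.  Torsion and Cartesian views are kept
consistent through :meth:`sync_torsions` and :meth:`rebuild_from_torsions`
(ideal-internal-coordinate chain growth in either direction).

Conventions: 1-based, strictly increasing residue numbering; coordinates in
angstroms; torsions in degrees in (-180, 180], NaN where undefined;
``omega[i]`` is the CA(i)-C(i)-N(i+1)-CA(i+1) torsion of the peptide bond
*following* residue i.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable

import numpy as np

from . import constants as k
from . import geometry as geom

logger = logging.getLogger(__name__)

# atom slots in the coords array
N, CA, C, O = 0, 1, 2, 3
ATOM_NAMES = ("N", "CA", "C", "O")

TAG_ALIGNED = "aligned"
TAG_REBUILT = "rebuilt"
TAG_GAP_FLANK = "gap-flank"


@dataclasses.dataclass
class BackboneModel:
    resnum: np.ndarray          # (n,) int, strictly increasing
    seq: np.ndarray             # (n,) '<U1'
    coords: np.ndarray          # (n, 4, 3) float, NaN = missing
    torsions: np.ndarray        # (n, 3) phi, psi, omega; NaN = undefined
    break_after: np.ndarray     # (n,) bool, explicit break between i and i+1
    movable: np.ndarray         # (n,) bool
    tags: np.ndarray            # (n,) '<U9'
    strained: bool = False

    # -- construction -----------------------------------------------------

    @classmethod
    def from_arrays(cls, resnum, seq, coords) -> "BackboneModel":
        resnum = np.asarray(resnum, dtype=int)
        n = len(resnum)
        if n == 0:
            raise ValueError("empty model")
        if np.any(np.diff(resnum) <= 0):
            raise ValueError("residue numbers must be strictly increasing")
        m = cls(
            resnum=resnum,
            seq=np.asarray(seq, dtype="<U1"),
            coords=np.asarray(coords, dtype=float).reshape(n, 4, 3),
            torsions=np.full((n, 3), np.nan),
            break_after=np.zeros(n, dtype=bool),
            movable=np.ones(n, dtype=bool),
            tags=np.full(n, TAG_ALIGNED, dtype="<U9"),
        )
        m.detect_breaks()
        m.sync_torsions()
        return m

    @classmethod
    def from_torsions(cls, seq: str, torsions, start_resnum: int = 1) -> "BackboneModel":
        """Grow an ideal-geometry chain from a torsion table.

        ``torsions`` is (n, 3) phi/psi/omega in degrees; phi of the first and
        psi/omega of the last residue are ignored (may be NaN).
        """
        seq = np.asarray(list(seq), dtype="<U1")
        n = len(seq)
        torsions = np.asarray(torsions, dtype=float).reshape(n, 3)
        coords = np.full((n, 4, 3), np.nan)
        # seed residue 0 in a canonical frame
        coords[0, N] = (0.0, 0.0, 0.0)
        coords[0, CA] = (k.BOND_N_CA, 0.0, 0.0)
        ang = np.radians(180.0 - k.ANGLE_N_CA_C)
        coords[0, C] = coords[0, CA] + k.BOND_CA_C * np.array(
            [np.cos(ang), np.sin(ang), 0.0]
        )
        m = cls(
            resnum=np.arange(start_resnum, start_resnum + n),
            seq=seq,
            coords=coords,
            torsions=torsions,
            break_after=np.zeros(n, dtype=bool),
            movable=np.ones(n, dtype=bool),
            tags=np.full(n, TAG_ALIGNED, dtype="<U9"),
        )
        if n > 1:
            m.rebuild_from_torsions(0, "n_to_c")
        m._place_oxygen(0, n - 1)
        m.sync_torsions()
        return m

    # -- basic accessors ---------------------------------------------------

    @property
    def n_res(self) -> int:
        return len(self.resnum)

    def copy(self) -> "BackboneModel":
        return BackboneModel(
            resnum=self.resnum.copy(),
            seq=self.seq.copy(),
            coords=self.coords.copy(),
            torsions=self.torsions.copy(),
            break_after=self.break_after.copy(),
            movable=self.movable.copy(),
            tags=self.tags.copy(),
            strained=self.strained,
        )

    def has_coords(self, i: int) -> bool:
        return bool(np.isfinite(self.coords[i, :3]).all())

    def index_of(self, resnum: int) -> int:
        idx = np.searchsorted(self.resnum, resnum)
        if idx >= self.n_res or self.resnum[idx] != resnum:
            raise KeyError(f"no residue numbered {resnum}")
        return int(idx)

    def ca(self) -> np.ndarray:
        return self.coords[:, CA]

    def backbone_atoms(self, which: Iterable[int] = (N, CA, C, O)) -> np.ndarray:
        """Flat (m, 3) array of the requested atom slots, finite rows only."""
        pts = self.coords[:, list(which)].reshape(-1, 3)
        return pts[np.isfinite(pts).all(axis=1)]

    # -- chain-break bookkeeping -------------------------------------------

    def bonded(self, i: int) -> bool:
        """True if residues i and i+1 are treated as chain-bonded."""
        if i < 0 or i >= self.n_res - 1:
            return False
        if self.break_after[i] or self.resnum[i + 1] != self.resnum[i] + 1:
            return False
        if not (np.isfinite(self.coords[i, C]).all() and np.isfinite(self.coords[i + 1, N]).all()):
            return False
        d = np.linalg.norm(self.coords[i + 1, N] - self.coords[i, C])
        return 0.5 < d < 3.0

    def detect_breaks(self) -> np.ndarray:
        """Record breaks wherever the C(i)-N(i+1) geometry is not chain-like."""
        for i in range(self.n_res - 1):
            numbering_gap = self.resnum[i + 1] != self.resnum[i] + 1
            missing = not (
                np.isfinite(self.coords[i, C]).all()
                and np.isfinite(self.coords[i + 1, N]).all()
            )
            if numbering_gap or missing:
                self.break_after[i] = True
                continue
            d = np.linalg.norm(self.coords[i + 1, N] - self.coords[i, C])
            if not (0.5 < d < 3.0):
                self.break_after[i] = True
        return self.break_after

    # -- torsion <-> Cartesian ---------------------------------------------

    def sync_torsions(self) -> None:
        """Recompute phi/psi/omega from coordinates where the four defining
        atoms exist and are chain-bonded; other entries are left untouched."""
        c = self.coords
        for i in range(self.n_res):
            if self.bonded(i - 1) if i > 0 else False:
                self.torsions[i, 0] = geom.dihedral(c[i - 1, C], c[i, N], c[i, CA], c[i, C])
            if i < self.n_res - 1 and self.bonded(i):
                self.torsions[i, 1] = geom.dihedral(c[i, N], c[i, CA], c[i, C], c[i + 1, N])
                self.torsions[i, 2] = geom.dihedral(c[i, CA], c[i, C], c[i + 1, N], c[i + 1, CA])

    def _place_oxygen(self, lo: int, hi: int) -> None:
        """(Re)place carbonyl O for residues lo..hi from current coordinates."""
        c = self.coords
        for i in range(lo, hi + 1):
            if not np.isfinite(c[i, :3]).all():
                continue
            if i < self.n_res - 1 and self.bonded(i):
                ref = c[i + 1, N]
                tors = 180.0
            else:
                ref = c[i, N]
                psi = self.torsions[i, 1]
                tors = geom.wrap_angle(psi - 180.0) if np.isfinite(psi) else 180.0
            c[i, O] = geom.place_atom(ref, c[i, CA], c[i, C], k.BOND_C_O, k.ANGLE_CA_C_O, tors)

    def rebuild_from_torsions(self, anchor: int, direction: str = "n_to_c",
                              stop: int | None = None) -> "BackboneModel":
        """Regenerate coordinates on one side of ``anchor`` from the stored
        torsions using ideal internal coordinates (in place).

        ``direction`` "n_to_c" rebuilds residues anchor+1..stop (default:
        chain end); "c_to_n" rebuilds stop..anchor-1 going backwards.  The
        anchor residue itself (and everything on its other side) is untouched.
        """
        if not 0 <= anchor < self.n_res:
            raise IndexError(f"anchor {anchor} out of range")
        if not self.has_coords(anchor):
            raise ValueError("anchor residue has no coordinates")
        c = self.coords
        t = np.where(np.isfinite(self.torsions), self.torsions, 180.0)
        if direction == "n_to_c":
            stop = self.n_res - 1 if stop is None else stop
            for i in range(anchor + 1, stop + 1):
                c[i, N] = geom.place_atom(c[i - 1, N], c[i - 1, CA], c[i - 1, C],
                                          k.BOND_C_N, k.ANGLE_CA_C_N, t[i - 1, 1])
                c[i, CA] = geom.place_atom(c[i - 1, CA], c[i - 1, C], c[i, N],
                                           k.BOND_N_CA, k.ANGLE_C_N_CA, t[i - 1, 2])
                c[i, C] = geom.place_atom(c[i - 1, C], c[i, N], c[i, CA],
                                          k.BOND_CA_C, k.ANGLE_N_CA_C, t[i, 0])
                self.break_after[i - 1] = False
            # the anchor residue (incl. its O) stays bitwise untouched
            self._place_oxygen(anchor + 1, stop)
        elif direction == "c_to_n":
            stop = 0 if stop is None else stop
            for i in range(anchor - 1, stop - 1, -1):
                c[i, C] = geom.place_atom(c[i + 1, C], c[i + 1, CA], c[i + 1, N],
                                          k.BOND_C_N, k.ANGLE_C_N_CA, t[i + 1, 0])
                c[i, CA] = geom.place_atom(c[i + 1, CA], c[i + 1, N], c[i, C],
                                           k.BOND_CA_C, k.ANGLE_CA_C_N, t[i, 2])
                c[i, N] = geom.place_atom(c[i + 1, N], c[i, C], c[i, CA],
                                          k.BOND_N_CA, k.ANGLE_N_CA_C, t[i, 1])
                self.break_after[i] = False
            self._place_oxygen(stop, anchor - 1)
        else:
            raise ValueError(f"unknown direction {direction!r}")
        return self

    # -- derived atoms ------------------------------------------------------

    def virtual_cb(self) -> np.ndarray:
        """(n, 3) side-chain interaction centres (virtual CB, all residues)."""
        return geom.virtual_cb(self.coords[:, N], self.coords[:, CA], self.coords[:, C])

    # -- diagnostics --------------------------------------------------------

    def bond_length_deviations(self) -> np.ndarray:
        """Absolute deviations of all backbone bonds from their ideals."""
        devs = []
        c = self.coords
        for i in range(self.n_res):
            if not self.has_coords(i):
                continue
            devs.append(abs(np.linalg.norm(c[i, CA] - c[i, N]) - k.BOND_N_CA))
            devs.append(abs(np.linalg.norm(c[i, C] - c[i, CA]) - k.BOND_CA_C))
            if np.isfinite(c[i, O]).all():
                devs.append(abs(np.linalg.norm(c[i, O] - c[i, C]) - k.BOND_C_O))
            if i < self.n_res - 1 and self.bonded(i):
                devs.append(abs(np.linalg.norm(c[i + 1, N] - c[i, C]) - k.BOND_C_N))
        return np.asarray(devs)

    def validate(self) -> None:
        if np.any(np.diff(self.resnum) <= 0):
            raise ValueError("residue numbers not strictly increasing")
        c = self.coords
        for i in range(self.n_res - 1):
            if self.break_after[i] or self.resnum[i + 1] != self.resnum[i] + 1:
                continue
            if not (np.isfinite(c[i, C]).all() and np.isfinite(c[i + 1, N]).all()):
                continue
            d = np.linalg.norm(c[i + 1, N] - c[i, C])
            if not (0.5 < d < 3.0):
                raise ValueError(
                    f"unrecorded chain break between residues {self.resnum[i]} "
                    f"and {self.resnum[i + 1]} (C-N distance {d:.2f} A)"
                )


@dataclasses.dataclass
class AlignmentSpec:
    """A template-to-target alignment with explicit gap bookkeeping.

    ``aligned_pairs`` holds (template residue number, target residue number)
    pairs, monotone in both coordinates.  ``gap_segments`` are the maximal
    runs of target residues absent from the alignment, stored as closed
    intervals (start, end, length).
    """

    template_sequence: str
    target_sequence: str
    aligned_pairs: list[tuple[int, int]]
    gap_segments: list[tuple[int, int, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        pairs = self.aligned_pairs
        for (t0, q0), (t1, q1) in zip(pairs, pairs[1:]):
            if t1 <= t0 or q1 <= q0:
                raise ValueError("aligned_pairs must be strictly monotone in both coordinates")
        if not self.gap_segments:
            self.gap_segments = self._derive_gaps()
        self._check_gaps()

    def _derive_gaps(self) -> list[tuple[int, int, int]]:
        aligned_q = {q for _, q in self.aligned_pairs}
        gaps = []
        run_start = None
        for q in range(1, len(self.target_sequence) + 1):
            if q not in aligned_q:
                if run_start is None:
                    run_start = q
            elif run_start is not None:
                gaps.append((run_start, q - 1, q - run_start))
                run_start = None
        if run_start is not None:
            q = len(self.target_sequence) + 1
            gaps.append((run_start, q - 1, q - run_start))
        return gaps

    def _check_gaps(self) -> None:
        if self.gap_segments != self._derive_gaps():
            raise ValueError("gap_segments are not the maximal unaligned runs")


def torsion_rmsd(t1: np.ndarray, t2: np.ndarray) -> float:
    """RMS of wrapped phi/psi differences between two (n, >=2) torsion sets."""
    d = geom.wrap_angle(np.asarray(t1, float)[:, :2] - np.asarray(t2, float)[:, :2])
    return float(np.sqrt(np.nanmean(d**2)))
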