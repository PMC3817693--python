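"""Profile-free fragment libraries and BLOSUM-weighted fragment picking.

Fragments are fixed-length windows of backbone torsions harvested from known
structures.  Picking for a target window ranks all fragments of matching
length by the summed BLOSUM substitution score between the target window
sequence and the fragment's source sequence — no sequence profile, no
secondary-structure prediction — which makes fragment generation a matter
of seconds instead of the hour-scale profile pipeline, at some cost in
fragment accuracy.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from Bio.Align import substitution_matrices

from . import constants as k
from .model import BackboneModel

logger = logging.getLogger(__name__)

FRAGMENT_LENGTHS = (3, 9)
DEFAULT_N_PICKS = 25


@dataclasses.dataclass(frozen=True)
class Fragment:
    length: int
    torsions: tuple  # length triples of (phi, psi, omega), degrees
    source_sequence: str
    source_id: str
    window_start: int  # 0-based window position within the source model

    def torsion_array(self) -> np.ndarray:
        return np.asarray(self.torsions, dtype=float).reshape(self.length, 3)


@dataclasses.dataclass
class FragmentLibrary:
    fragments: dict  # length -> list[Fragment]
    metadata: str = ""

    def of_length(self, length: int) -> list:
        return self.fragments.get(length, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self.fragments.values())

    def add(self, frag: Fragment) -> None:
        self.fragments.setdefault(frag.length, []).append(frag)


class SubstitutionMatrix:
    """Symmetric amino-acid substitution scores (BLOSUM62 by default)."""

    def __init__(self, scores: dict[tuple[str, str], float], name: str):
        self.name = name
        self._scores = scores
        self._check()

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        raw = substitution_matrices.load("BLOSUM62")
        scores = {}
        for a in raw.alphabet:
            for b in raw.alphabet:
                scores[(a, b)] = float(raw[a, b])
        return cls(scores, "BLOSUM62")

    def _check(self) -> None:
        for (a, b), v in self._scores.items():
            if abs(v - self._scores[(b, a)]) > 0:
                raise ValueError(f"{self.name}: asymmetric at ({a},{b})")
        # diagonal dominance over the 20 standard residues (holds for
        # BLOSUM62 row-wise: no off-diagonal entry beats the diagonal)
        for a in k.AA1:
            diag = self._scores[(a, a)]
            for b in k.AA1:
                if self._scores[(a, b)] > diag:
                    raise ValueError(f"{self.name}: ({a},{b}) exceeds diagonal")

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[(a, b)]
        except KeyError:
            if ("X", "X") in self._scores:
                xa = a if (a, "X") in self._scores else "X"
                xb = b if (xa, b) in self._scores else "X"
                return self._scores[(xa, xb)]
            raise ValueError(f"no substitution score for pair ({a},{b})")


def build_library(models: list[BackboneModel], length: int,
                  metadata: str = "") -> FragmentLibrary:
    """Extract one fragment per contiguous (break-free) window per model.

    Windows are all n-length+1 start positions; chain breaks inside a window
    disqualify it.  Undefined terminal torsions (phi of the chain start, psi
    and omega of the chain end) are replaced by extended-coil values so every
    stored fragment has a complete torsion table.
    """
    if length < 2:
        raise ValueError("fragment length must be >= 2")
    lib = FragmentLibrary({}, metadata=metadata)
    for im, m in enumerate(models):
        source = f"model{im:03d}"
        tors = m.torsions.copy()
        fill = np.array([k.EXTENDED_PHI_PSI[0], k.EXTENDED_PHI_PSI[1], 180.0])
        tors = np.where(np.isfinite(tors), tors, fill)
        for start in range(0, m.n_res - length + 1):
            window = slice(start, start + length)
            if any(m.break_after[i] for i in range(start, start + length - 1)):
                continue
            if not all(m.has_coords(i) for i in range(start, start + length)):
                continue
            lib.add(Fragment(
                length=length,
                torsions=tuple(map(tuple, tors[window])),
                source_sequence="".join(m.seq[window]),
                source_id=source,
                window_start=start,
            ))
    if len(lib) == 0:
        raise ValueError("no valid fragment windows in the given models")
    return lib


def score_fragment(query_window: str, frag: Fragment,
                   matrix: SubstitutionMatrix,
                   as_distance: bool = False) -> float:
    """Summed substitution score between the query window and the fragment's
    source sequence (higher is better; ``as_distance`` negates)."""
    if len(query_window) != frag.length:
        raise ValueError("query window length != fragment length")
    s = sum(matrix.score(q, f)
            for q, f in zip(query_window, frag.source_sequence))
    return -s if as_distance else s


def pick_fragments(query_window: str, library: FragmentLibrary,
                   n_picks: int = DEFAULT_N_PICKS,
                   matrix: SubstitutionMatrix | None = None) -> list[Fragment]:
    """The ``n_picks`` best-scoring fragments for the query window,
    deterministically ordered (score desc, then source_id / window start)."""
    if matrix is None:
        matrix = SubstitutionMatrix.blosum62()
    frags = library.of_length(len(query_window))
    if not frags:
        raise ValueError(f"library has no fragments of length {len(query_window)}")
    if n_picks > len(frags):
        logger.warning("requested %d picks but library holds %d fragments",
                       n_picks, len(frags))
    ranked = sorted(
        frags,
        key=lambda f: (-score_fragment(query_window, f, matrix),
                       f.source_id, f.window_start),
    )
    return ranked[:max(n_picks, 0)]


# ---------------------------------------------------------------------------
# Text format: per length a header "length count", then per fragment a line
# "source_id window_start sequence" followed by `length` lines of phi psi
# omega.  Plain text so externally generated fragments can be plugged in.
# ---------------------------------------------------------------------------

def write_library(lib: FragmentLibrary, path) -> None:
    with open(path, "w") as fh:
        if lib.metadata:
            fh.write(f"# {lib.metadata}\n")
        for length in sorted(lib.fragments):
            frags = lib.fragments[length]
            fh.write(f"{length} {len(frags)}\n")
            for f in frags:
                fh.write(f"{f.source_id} {f.window_start} {f.source_sequence}\n")
                for phi, psi, omega in f.torsions:
                    fh.write(f"{phi:.3f} {psi:.3f} {omega:.3f}\n")


def read_library(path) -> FragmentLibrary:
    lib = FragmentLibrary({})
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh
                 if ln.strip() and not ln.startswith("#")]
    pos = 0
    while pos < len(lines):
        length, count = (int(v) for v in lines[pos].split())
        pos += 1
        for _ in range(count):
            source_id, window_start, seq = lines[pos].split()
            pos += 1
            tors = []
            for _ in range(length):
                tors.append(tuple(float(v) for v in lines[pos].split()))
                pos += 1
            lib.add(Fragment(length, tuple(tors), seq, source_id,
                             int(window_start)))
    if len(lib) == 0:
        raise ValueError(f"{path}: empty fragment library")
    return lib
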