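# Methods

This note documents the models, algorithms and parameter choices in
`densloop`, the assumptions behind the synthetic benchmark, and the known
limitations.  Units: lengths in Å, angles in degrees, energies in
arbitrary "energy units" (only weight ratios matter).

## Structure representation

A `BackboneModel` stores one chain at backbone resolution — N, CA, C, O per
residue — plus (φ, ψ, ω) torsions, an explicit chain-break table, a
movability mask and per-residue provenance tags.  ω(i) is the torsion of
the peptide bond *following* residue i.  Coordinates are regenerated from
torsions by NeRF-style internal-coordinate growth in either chain
direction, using ideal internal coordinates (N–CA 1.458, CA–C 1.525,
C–N 1.329, C=O 1.231; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°,
CA–C–O 120.8°).  Carbonyl O is placed trans-planar to the next N.  The
torsion↔Cartesian round trip is exact to 1e-6°/1e-4 Å in memory; through
a PDB file it is limited by the format's 3-decimal coordinates to ~0.04°.

Only single chains and orthogonal (P1-box) maps are supported; residues
with insertion codes are skipped with a warning and alternate conformers
keep the first copy.  Side chains beyond a virtual CB are out of scope.

Derived atoms are closed forms chosen for exact, cheap Jacobians:

* virtual CB (the side-chain interaction centre, built for every residue
  including glycine): the standard tetrahedral construction
  `CB = CA − 0.58273431 (b×c) + 0.56802827 b − 0.54067466 c` with
  `b = CA−N`, `c = C−CA` — polynomial in the backbone coordinates;
* amide H: `N + 1.01 · unit(2N − CA − C_prev)` (one normalisation).

## Low-resolution energy

Each term is a smooth analytic stand-in that honours the qualitative
behaviour expected of a backbone-level score; all gradients are analytic
and are tested against central differences at 1e-4 relative.

* **Ramachandran** — E = −log P(φ,ψ), P a periodic mixture of Gaussian
  basins (α at (−63,−43), σ 14°; β at (−120,130), σ (22,26)°; left-α at
  (57,47), σ 13°; weights 1.0/0.8/0.2) over a uniform floor 1e-5.  The
  proline-specific basin is deliberately omitted.
* **Soft-sphere repulsion** — k(r₀−d)² for d<r₀ over atom pairs from
  residues ≥2 apart, with reduced radii (N/O 1.35, C/CA 1.60, CB 1.80) so
  hydrogen-bonded backbone contacts are not penalised; k=1.
* **Backbone H-bond** — per donor–acceptor pair
  −depth · exp(−(d_HO−1.9)²/(2·0.3²)) · max(0,−cos∠N–H···O)², cutoff
  4.0 Å (the Gaussian is ~2e-11 of depth there), separation ≥2.  A "well"
  is counted when a pair's energy is below −0.1·depth; ideal helices show
  the i,i+4 ladder (≈ L−4 wells) and the relaxed E-T-E element of the
  generator forms the antiparallel ladder of a β-hairpin.
* **Bond geometry** — harmonic restraints on all backbone bond lengths
  (k_len 200 /Å²), bond angles (k_ang 20 /rad²) and ω-planarity
  (k_ω 10 /rad²), *including* the inter-residue C–N bond for every
  consecutively numbered pair with coordinates, whether or not a break is
  recorded: open junctions are thereby penalised and pulled closed by
  minimization rather than being forbidden.  k_len = 200 was set so that
  the strongest density pull on a single atom (weight 2, unit-SD map)
  equilibrates well below the 0.05 Å healing bound.
* **Density** — see below.

Default weights: rama 0.5, vdw 1.0, hbond_bb 1.0, cart_bonded 1.0,
density 2.0.  All weights and parameters are plain constants plus a YAML
override file (`densloop score --weights`); they are package choices, not
fitted quantities.

## Density simulation and scoring

Atoms are isotropic Gaussians with σ = resolution/(π√2) and amplitudes
proportional to electron counts, normalised to carbon = 1 (N 7/6, O 8/6,
CB 1) so that score fields over a standardized (zero-mean, unit-SD) map
stay on an O(1) scale.  Each residue contributes N, CA, C, O and the
virtual CB.  Simulated maps are evaluated within 4.5 σ of each atom;
sampling must satisfy spacing ≤ resolution/3.

**Masked score** — for each residue, the Pearson correlation of simulated
vs observed density over voxels within 3.2 Å of any of its atoms
(mask recomputed from current coordinates every call); the total score is
the negative mean.  Residues with empty masks are reported as missing and
excluded.

**Fast score** — for each atom type, the cross-correlation
(kernel ⋆ ρ_obs) is computed once over the whole map by multiplying the
map's FFT with the kernel's analytic transform, on a 2× Fourier-upsampled
grid ("dense grid sampling"; at map spacing = resolution/3 the field is
then sampled at resolution/6).  A tricubic B-spline (periodic prefilter,
wrap boundary) gives values and analytic gradients per atom; the score is
−Σ_atoms field(x) with no per-pose normalisation.  Evaluation points are
clamped to a 2-voxel interior margin with a clamp counter, so refinement
excursions degrade gracefully.  Agreement with the brute-force real-space
sum is ~4e-5 relative on a 0.5 Å-sampled map; on a map sampled at
resolution/3 the band-limiting discrepancy of the spectral route reaches
~2 % — the oracle check therefore uses the finer sampling.  The spline
is exact at grid nodes and its analytic gradient matches finite
differences to better than 1e-4.  Per-call cost is linear in the atom
count and independent of map size (≥5× faster than the masked score on a
100-residue case, typically far more).

## Chain closure (CCD)

`ccd_close` closes a break at a cutpoint against the N/CA/C anchors of the
next residue, rotating one movable φ/ψ at a time by the closed-form
optimal angle (Canutescu–Dunbrack style), capped at 60° per step, ω held
trans.  Sweeps cover **both** sides of the cutpoint by default: measured
on mid-segment cutpoints, single-sided sweeps stall near 0.14 Å RMS on a
single-torsion break after 30 sweeps, while two-sided sweeps close it in
~4; a flag restores single-direction sweeps.  Defaults: tol 0.08 Å RMS
over the three anchors, 100 sweeps.  The anchor deviation is
non-increasing by construction, and bond lengths/angles are preserved to
float rounding (the junction bond itself, of course, changes — that is the
closure).  No Ramachandran or clash filtering happens inside CCD; the
strained geometry this can leave behind is an intended, faithful property
of the geometric-closure protocol.

## Cartesian minimization and healing

`cartesian_minimize` runs L-BFGS-B on the Cartesian coordinates of movable
residues with the analytic total gradient (gtol 1e-4); the returned energy
never exceeds the input, frozen residues are bitwise untouched, and break
flags are re-derived from the final geometry.  `heal_insertion` minimises
with *all* residues movable after a fragment splice; the bond-geometry
term pulls the window junctions closed (typically to <0.02 Å within a
250–400-evaluation budget) and a `strained` flag is set if the 0.05 Å
bound is not reached.  Torsion-space minimization is deliberately absent.

## Rebuild protocols

Threading maps the template onto the target (aligned residues renumbered
and mutated, unaligned residues dropped); gap segments are the maximal
unaligned runs.  Segments of ≤8 residues are rebuilt left-to-right, each
with its own child RNG stream (so segments are sampled independently and
the trajectory is bitwise reproducible from the seed); terminal gaps (one
anchor) and longer gaps are left as recorded breaks with a warning.  Gap
residues are initialised by extended-torsion growth from both anchors plus
one CCD closure.  Fragment picks (default 25 per window, BLOSUM62) use
3-mers for gaps of ≤4 residues, else 9-mers; windows must overlap the gap
and fit within the flank-extended span (default flank 3, range 2–5).

* **2011** — per cycle: set fragment torsions into a random window,
  regenerate coordinates from both anchors toward the mid-segment
  cutpoint, CCD-close, score (low-resolution energy + density), Metropolis
  accept/reject at T=2.0 with ×0.95 geometric cooling every 20 cycles.
  Unclosable proposals are skipped.  Aligned residues outside the flanks
  are bitwise frozen, including during the final relax, which is
  restricted to the movable mask.
* **2013** — per cycle: build the fragment from its torsions, superpose it
  rigidly (Kabsch over N/CA/C of the window's end overlap residues),
  splice, heal by whole-structure minimization, Metropolis.  The final
  relax is whole-structure.  Density enters both the Monte Carlo score and
  the healing gradient.

The Monte Carlo density term uses the fast score by default; a flag
substitutes the masked correlation (scaled ×100 so the configured weight
is comparable across routes).  Each trajectory returns the best accepted
model and a per-cycle record (scores, acceptance), surfaced through the
`LoopRebuilder` / `RebuildResults` front end.

## Evaluation

`model_map_cc` is the Pearson correlation between model-simulated and
reference density after hard Fourier truncation at a 3 Å resolution limit
(no B-factor sharpening).  `ensemble_stats` reports the average, best and
*selected* CC, where selection takes the best `k` models by an independent
selector — here a fast density score on a **held-out** selection map
(different noise draw and resolution from both the guidance map and the
evaluation reference), standing in for ranking against unphased data.
`cc_vs_samples` gives the expected selected-model CC as a function of the
number of models generated, either by averaging random orderings or in
closed form (the first N of a random permutation is a uniform N-subset;
the subset's pick is its selector-best member).  The exact curve is used
in the acceptance checks to avoid permutation noise.

## Synthetic benchmark

`make_topology` builds chains from secondary-structure strings
(H/E/L plus a 2-residue turn element T), with basin torsions + 3° Gaussian
noise, loop torsions drawn from a small coil set and resampled until no
soft-sphere clash involves a loop residue, followed by a relaxation under
the no-density energy (which is what folds an E-T-E stretch into a
genuinely hydrogen-bonded hairpin).  `make_template` corrupts a truth:
rigid loop displacement, segment deletion, or a register-shift alignment
that inserts k unaligned residues inside a strand and maps every later
residue k positions back — the classic misalignment-in-a-strand scenario.
`make_noisy_map` blends truth and template densities
((1−b)·truth + b·template, b = 0.3 by default, standing in for model
bias) plus Gaussian voxel noise whose level is bisected until the
truth-map correlation hits a requested target ±0.02; maps are
standardized.

The three packaged cases (54–60 residues, 3 Å maps sampled at 1 Å,
target input CC 0.40 — the package's notion of a medium-difficulty
starting map):

* **gap** — helical/hairpin topology with a clean 6-residue loop deletion;
* **register** — a β-hairpin with a +2 register shift placing the
  insertion inside the second strand;
* **loop** — a 10-residue loop whose first six residues are displaced
  4 Å *and aligned* (so the torsion-insertion protocol freezes them
  wrong), next to a 5-residue deletion that gets rebuilt.

Fragment libraries mix near-native fragments (truth torsions + 5° noise,
five variants per window overlapping each gap) with ~10× decoy fragments
harvested from unrelated random topologies; generation asserts that a
fragment within 10° mean torsion deviation of each gap's native window is
present.  Everything is byte-reproducible from the seed.

What the generator does **not** emulate: crystallographic symmetry and
reciprocal-space noise structure (no structure factors — noise is additive
Gaussian in real space), solvent, side chains, multi-chain packing, and
the scale of real benchmarks (hundreds of residues, CCs measured through
map coefficients).  Passing the synthetic comparisons therefore shows the
machinery behaves as designed — off-template movement repairs placed
misalignments and displaced loops that a frozen-template protocol cannot —
not that the absolute CC values transfer to real crystallographic data.

## Problem sizes in the checks

The acceptance checks run the two-protocol comparison with ten seeds per
protocol per case at 12 Monte Carlo cycles per segment and a
250-evaluation healing budget (production defaults are 200 cycles and
400/2000-evaluation budgets).  Both protocols get the same cycle budget —
a like-for-like comparison; an earlier asymmetric budget let the
torsion-insertion protocol exhaust its small proposal space and collapse
all seeds onto one model.  The sampling-efficiency plateau (smallest N
whose expected selected CC is within 0.02 of the full-ensemble value) is
compared as the median over the three cases, mirroring how a multi-case
benchmark is summarised; on a single case the statistic can degenerate
when a protocol's whole CC range is narrower than the 0.02 tolerance
(as happens for the frozen-template protocol on the displaced-loop case,
whose ceiling is capped by the mispositioned loop).

## Known limitations

* The energy is a qualitative stand-in: no statistics were fitted to
  structural databases, and absolute energies are not comparable to any
  published force field.
* Template movement is handled by local minimization, so large coordinated
  errors beyond the density's attraction basin can leave the model stuck
  in a local minimum; the displaced-loop case works through chain
  connectivity with the rebuilt gap plus the truth-weighted density.
* The fast score drops per-pose normalisation entirely; it tracks the
  unmasked correlation in rank (Spearman ρ ≥ 0.9 on random perturbations)
  but is not a correlation coefficient.
* The register-shift threading leaves the k shifted C-terminal residues
  unaligned at the chain end; terminal gaps are not rebuilt.
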