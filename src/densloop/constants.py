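"""Ideal backbone internal coordinates and energy-term parameter tables.

All lengths in angstroms, angles and torsions in degrees, energies in
arbitrary "energy units" (the low-resolution score is a relative quantity;
only ratios of term weights matter).
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Ideal backbone geometry (Engh & Huber-style ideals used for chain growth,
# CCD closure and the bond-geometry restraint term).
# ---------------------------------------------------------------------------

BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329  # inter-residue peptide bond
BOND_C_O = 1.231
BOND_N_H = 1.010
BOND_CA_CB = 1.530

ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2  # CA(i)-C(i)-N(i+1)
ANGLE_C_N_CA = 121.7  # C(i)-N(i+1)-CA(i+1)
ANGLE_CA_C_O = 120.8
# O, N(i+1) coplanar on opposite sides of C: O-C-N closes the circle.
ANGLE_O_C_N = 360.0 - ANGLE_CA_C_N - ANGLE_CA_C_O

OMEGA_IDEAL = 180.0

# Standard torsion presets.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)
EXTENDED_PHI_PSI = (-120.0, 120.0)

# ---------------------------------------------------------------------------
# Density / atom kernel parameters.
# Amplitudes are proportional to electron counts (carbon = 1, so the score
# field stays on an O(1) scale against a standardized map); the CB
# pseudo-atom stands in for the whole side chain at carbon weight.
# ---------------------------------------------------------------------------

ATOM_TYPES = ("N", "CA", "C", "O", "CB")
ATOM_ELECTRONS = {"N": 7.0 / 6.0, "CA": 1.0, "C": 1.0, "O": 8.0 / 6.0,
                  "CB": 1.0}

# ---------------------------------------------------------------------------
# Energy-term parameters.
# ---------------------------------------------------------------------------

# Soft-sphere repulsion radii (reduced vs van der Waals so that backbone
# hydrogen-bonded contacts are not penalised).
VDW_RADII = {"N": 1.35, "CA": 1.60, "C": 1.60, "O": 1.35, "CB": 1.80}
VDW_K = 1.0  # energy units / A^2
VDW_MIN_SEQ_SEP = 2  # |i - j| >= 2

# Backbone H-bond well: depth * gauss(d_HO; 1.9, 0.3) * max(0, -cos(N-H..O))^2
HBOND_DEPTH = 1.0
HBOND_D0 = 1.9
HBOND_SIGMA = 0.3
HBOND_CUTOFF = 4.0  # A on the H..O distance; Gaussian ~ 2e-11 of depth there
HBOND_MIN_SEQ_SEP = 2

# Bond-geometry restraints.
CART_K_LENGTH = 200.0  # energy units / A^2
CART_K_ANGLE = 20.0    # energy units / rad^2
CART_K_OMEGA = 10.0    # energy units / rad^2

# Ramachandran mixture: weight, (phi0, psi0), (sigma_phi, sigma_psi) degrees.
RAMA_BASINS = (
    (1.00, (-63.0, -43.0), (14.0, 14.0)),    # alpha
    (0.80, (-120.0, 130.0), (22.0, 26.0)),   # beta
    (0.20, (57.0, 47.0), (13.0, 13.0)),      # left-handed alpha
)
RAMA_FLOOR = 1.0e-5

# Default term weights for the combined low-resolution objective.
DEFAULT_WEIGHTS = {
    "rama": 0.5,
    "vdw": 1.0,
    "hbond_bb": 1.0,
    "cart_bonded": 1.0,
    "density": 2.0,
}

AA1 = "ACDEFGHIKLMNPQRSTVWY"

AA_3TO1 = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
AA_1TO3 = {v: k for k, v in AA_3TO1.items()}
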