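"""Shared constant tables: alphabet, background composition, radii, reference SASA.

All tables are plain Python objects so callers can copy and override them;
nothing in the package mutates them.
"""

from __future__ import annotations

import numpy as np

#: Canonical amino-acid alphabet order used for every frequency vector/matrix.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Index of the gap symbol in integer-encoded alignments (residues are 0..19).
GAP_CODE = 20

GAP_CHAR = "-"

#: Ambiguity / nonstandard one-letter codes normalized to gap for statistics.
NONSTANDARD_AA = set("BZXJUO")

#: Background amino-acid composition (order = AA_ALPHABET).  This is the
#: composition table used by the published SCA toolbox lineage; it is
#: normalized here so it sums to exactly 1.
_BG = np.array(
    [
        0.073, 0.025, 0.050, 0.061, 0.042, 0.072, 0.023, 0.053, 0.064, 0.089,
        0.023, 0.043, 0.052, 0.040, 0.052, 0.073, 0.056, 0.063, 0.013, 0.033,
    ]
)
BACKGROUND_COMPOSITION = _BG / _BG.sum()

#: Default pseudocount fraction for frequency regularization.
DEFAULT_PSEUDOCOUNT = 0.03

#: Van der Waals radii by element symbol (Angstrom).
VDW_RADII = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "XE": 2.16,
    "FE": 1.80,
    "ZN": 1.39,
    "MG": 1.73,
    "CA": 2.31,
    "MN": 1.80,
    "NA": 2.27,
    "K": 2.75,
}

#: Fallback radius for unknown elements (a warning is emitted when used).
DEFAULT_VDW_RADIUS = 1.70

#: Water-probe radius (Angstrom).
DEFAULT_PROBE_RADIUS = 1.4

#: Theoretical maximum solvent accessibility per residue (Angstrom^2),
#: the Gly-X-Gly tripeptide reference values of Tien et al.
MAX_SASA = {
    "ALA": 129.0,
    "ARG": 274.0,
    "ASN": 195.0,
    "ASP": 193.0,
    "CYS": 167.0,
    "GLN": 225.0,
    "GLU": 223.0,
    "GLY": 104.0,
    "HIS": 224.0,
    "ILE": 197.0,
    "LEU": 201.0,
    "LYS": 236.0,
    "MET": 224.0,
    "PHE": 240.0,
    "PRO": 159.0,
    "SER": 155.0,
    "THR": 172.0,
    "TRP": 285.0,
    "TYR": 263.0,
    "VAL": 174.0,
}

#: Relative-SASA threshold below which a residue counts as buried.
DEFAULT_BURIAL_THRESHOLD = 0.25

#: Rectangular Ramachandran regions (degrees): (phi_min, phi_max, psi_min, psi_max).
ALPHA_REGION = (-100.0, -30.0, -80.0, -5.0)
BETA_REGION = (-180.0, -45.0, 45.0, 180.0)

AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
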