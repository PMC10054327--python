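"""Constant lookup tables used across the feature-extraction modules.

Everything here is a fixed data constant: van der Waals radii, the
hydrophobic/polar residue partition, intrinsic side-chain pKa values,
secondary-structure propensities, a hydropathy scale, and the residue
contact potential used by the pseudo-energy descriptor.
"""

from __future__ import annotations

import numpy as np

#: PSI-BLAST column order of the 20 standard amino acids.
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

#: 3-letter -> 1-letter codes for the 20 standard residues.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: van der Waals radii in Angstrom by element symbol (Bondi-style values).
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85,
    "I": 1.98, "FE": 1.80, "ZN": 1.39, "MG": 1.73, "CA": 2.00,
}
DEFAULT_VDW_RADIUS = 1.70

#: Binary hydrophobic/polar partition used for shell amino-acid composition.
#: Hydrophobic set follows the common binary-patterning convention; the
#: remaining 11 standard residues are polar.  Configurable at call sites.
HYDROPHOBIC_RESIDUES = frozenset("ACFILMVWY")
DEFAULT_HP_TABLE = {
    aa: ("H" if aa in HYDROPHOBIC_RESIDUES else "P") for aa in PSSM_ALPHABET
}

#: Model (intrinsic) side-chain pKa values for ionizable residues, used by
#: the built-in fallback when no external pKa predictor report is supplied.
INTRINSIC_PKA = {
    "D": 3.8, "E": 4.5, "H": 6.5, "C": 9.0, "Y": 10.0, "K": 10.5, "R": 12.5,
}
IONIZABLE_RESIDUES = frozenset(INTRINSIC_PKA)

#: Chou-Fasman-style conformational propensities (helix, strand, turn).
#: The turn column doubles as a coil propensity in the fallback predictor.
CHOU_FASMAN = {
    #      helix  strand  turn
    "A": (1.42, 0.83, 0.66),
    "R": (0.98, 0.93, 0.95),
    "N": (0.67, 0.89, 1.56),
    "D": (1.01, 0.54, 1.46),
    "C": (0.70, 1.19, 1.19),
    "Q": (1.11, 1.10, 0.98),
    "E": (1.51, 0.37, 0.74),
    "G": (0.57, 0.75, 1.56),
    "H": (1.00, 0.87, 0.95),
    "I": (1.08, 1.60, 0.47),
    "L": (1.21, 1.30, 0.59),
    "K": (1.16, 0.74, 1.01),
    "M": (1.45, 1.05, 0.60),
    "F": (1.13, 1.38, 0.60),
    "P": (0.57, 0.55, 1.52),
    "S": (0.77, 0.75, 1.43),
    "T": (0.83, 1.19, 0.96),
    "W": (1.08, 1.37, 0.96),
    "Y": (0.69, 1.47, 1.14),
    "V": (1.06, 1.70, 0.50),
}

#: Kyte-Doolittle hydropathy scale; more positive = more hydrophobic.
HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Same-residue contact energies (RT units) from the Miyazawa-Jernigan
# statistical potential.  The full pair table is approximated below by the
# additive (hydrophobic-factorization) form e(a,b) = (e_aa + e_bb) / 2,
# which captures the dominant one-body structure of the potential.
_MJ_DIAGONAL = {
    "C": -5.44, "M": -5.46, "F": -7.26, "I": -6.54, "L": -7.04,
    "V": -5.52, "W": -5.06, "Y": -4.17, "A": -2.72, "G": -2.24,
    "T": -2.12, "S": -1.67, "N": -1.68, "Q": -1.54, "D": -1.60,
    "E": -1.51, "H": -3.05, "R": -1.55, "K": -0.12, "P": -1.75,
}


def contact_energy_table() -> np.ndarray:
    """Symmetric 20x20 residue contact potential in PSSM alphabet order."""
    diag = np.array([_MJ_DIAGONAL[aa] for aa in PSSM_ALPHABET])
    return (diag[:, None] + diag[None, :]) / 2.0


def contact_energy(table: np.ndarray, a: str, b: str) -> float:
    """Look up e(a, b); unknown residues contribute the mean energy."""
    idx = {aa: i for i, aa in enumerate(PSSM_ALPHABET)}
    if a not in idx or b not in idx:
        return float(table.mean())
    return float(table[idx[a], idx[b]])
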