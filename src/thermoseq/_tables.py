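"""Versioned per-residue constant tables backing the descriptor engine.

These tables are the contract for the feature definitions: any substitution
must keep the descriptor invariant tests green. Alphabetical one-letter
order (ACDEFGHIKLMNPQRSTVWY) throughout.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# average residue masses (Da, residue = amino acid minus water)
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

# Kyte–Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# van der Waals volume of the residue (A^3)
VDW_VOLUME = {
    "A": 67.0, "C": 86.0, "D": 91.0, "E": 109.0, "F": 135.0,
    "G": 48.0, "H": 118.0, "I": 124.0, "K": 135.0, "L": 124.0,
    "M": 124.0, "N": 96.0, "P": 90.0, "Q": 114.0, "R": 148.0,
    "S": 73.0, "T": 93.0, "V": 105.0, "W": 163.0, "Y": 141.0,
}

# approximate side-chain formal charge at pH 7 (H carries a small positive
# fractional charge from its partially protonated imidazole)
FORMAL_CHARGE = {aa: 0.0 for aa in AMINO_ACIDS}
FORMAL_CHARGE.update({"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0})

# Grantham polarity
GRANTHAM_POLARITY = {
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2,
    "G": 9.0, "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9,
    "M": 5.7, "N": 11.6, "P": 8.0, "Q": 10.5, "R": 10.5,
    "S": 9.2, "T": 8.6, "V": 5.9, "W": 5.4, "Y": 6.2,
}

# aromatic side chains
AROMATICITY = {aa: (1.0 if aa in "FWY" else 0.0) for aa in AMINO_ACIDS}

POSITIVE_RESIDUES = "KRH"
NEGATIVE_RESIDUES = "DE"
AROMATIC_RESIDUES = "FWY"
POLAR_RESIDUES = "CDEHKNQRSTY"     # charged + H-bonding side chains
NONPOLAR_RESIDUES = "AFGILMPVW"

# ---------------------------------------------------------------------------
# CTD: 7 physicochemical attributes, each partitioning the alphabet into
# 3 classes (composition 7*3=21, transition 7*3=21, distribution 7*15=105)
# ---------------------------------------------------------------------------
CTD_ATTRIBUTES = (
    "hydrophobicity",
    "vdw_volume",
    "polarity",
    "polarizability",
    "charge",
    "secondary_structure",
    "solvent_accessibility",
)

CTD_CLASSES: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MSPTHY"),
}

# ---------------------------------------------------------------------------
# PseAAC source properties (standardized over the alphabet at use time)
# ---------------------------------------------------------------------------
PSEAAC_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

# Hopp–Woods hydrophilicity
PSEAAC_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}

PSEAAC_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0,
    "G": 1.0, "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0,
    "M": 75.0, "N": 58.0, "P": 42.0, "Q": 72.0, "R": 101.0,
    "S": 31.0, "T": 45.0, "V": 43.0, "W": 130.0, "Y": 107.0,
}

# per-residue properties for the 6-channel hybrid residue encoding
RESIDUE_ENCODING_PROPERTIES = (
    ("weight", RESIDUE_MASS),
    ("charge", FORMAL_CHARGE),
    ("polarity", GRANTHAM_POLARITY),
    ("aromaticity", AROMATICITY),
    ("hydrophobicity", KYTE_DOOLITTLE),
    ("vdw_volume", VDW_VOLUME),
)
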