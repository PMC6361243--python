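"""Static lookup tables shared across modules.

The residue alphabet used throughout the package has 22 symbols: the 20
standard amino acids in alphabetical one-letter order, then ``X`` for any
nonstandard residue and ``-`` for the padding/gap symbol used by sliding
windows.
"""

from __future__ import annotations

import numpy as np

#: 22-symbol alphabet: 20 standard residues (alphabetical), X, gap.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY" + "X" + "-"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
N_SYMBOLS = len(AA_ALPHABET)
X_INDEX = AA_INDEX["X"]
GAP_INDEX = AA_INDEX["-"]

#: Standard 20 residues only (alphabetical one-letter order).
STANDARD_AAS = AA_ALPHABET[:20]

# Three-letter -> one-letter mapping. MSE (selenomethionine) maps to M, a
# handful of other common modified residues map to their parent; anything
# else nonstandard maps to X at load time.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # Common modified residues mapped to their parent amino acid.
    "MSE": "M", "SEC": "C", "PYL": "K", "HYP": "P", "SEP": "S",
    "TPO": "T", "PTR": "Y", "CSO": "C", "MLY": "K", "M3L": "K",
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
    "X": "UNK",
}

#: Kyte-Doolittle hydropathy scale; X and gap score 0 (neutral).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0, "-": 0.0,
}

#: Theoretical maximum solvent accessible surface area per residue type
#: (Angstrom^2), Tien et al. 2013 ("theoretical" column). X falls back to
#: the 20-residue mean.
MAX_ASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}
MAX_ASA["X"] = float(np.mean(list(MAX_ASA.values())))

#: Van der Waals radii (Angstrom) by element for SASA; fallback 1.80.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90,
    "P": 1.80, "H": 1.20,
}
DEFAULT_VDW_RADIUS = 1.80

#: Water-probe radius for rolling-sphere SASA (Angstrom).
SASA_PROBE_RADIUS = 1.4

#: Background amino-acid frequencies (Robinson & Robinson), indexed by the
#: alphabetical 20-letter order of AA_ALPHABET[:20].
BACKGROUND_FREQS = np.array([
    0.07805, 0.01925, 0.05364, 0.06295, 0.03856,  # A C D E F
    0.07377, 0.02199, 0.05142, 0.05744, 0.09019,  # G H I K L
    0.02243, 0.04487, 0.05203, 0.04264, 0.05129,  # M N P Q R
    0.07120, 0.05841, 0.06441, 0.01330, 0.03216,  # S T V W Y
])
BACKGROUND_FREQS = BACKGROUND_FREQS / BACKGROUND_FREQS.sum()

#: PSI-BLAST PSSM column order and its mapping into alphabetical order.
PSIBLAST_ORDER = "ARNDCQEGHILKMFPSTWYV"
PSIBLAST_TO_ALPHA = np.array([AA_INDEX[a] for a in PSIBLAST_ORDER])


def aa_from_resname(resname: str) -> str:
    """Map a PDB residue name to a one-letter code (nonstandard -> X)."""
    return THREE_TO_ONE.get(resname.strip().upper(), "X")
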