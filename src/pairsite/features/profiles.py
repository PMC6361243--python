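"""Sequence-derived residue features: one-hot identity, profile columns,
conservation.

Profile columns follow the PSI-BLAST ASCII PSSM convention: per position a
row of 20 integer log-odds scores and a row of 20 integer percentages
(weighted observed frequencies).  Columns are re-ordered internally to the
package's alphabetical amino-acid order.  When no profile file is supplied
a deterministic pseudo-profile is derived from BLOSUM62.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Align import substitution_matrices

from .._tables import (
    AA_ALPHABET,
    AA_INDEX,
    BACKGROUND_FREQS,
    GAP_INDEX,
    N_SYMBOLS,
    PSIBLAST_ORDER,
    PSIBLAST_TO_ALPHA,
    STANDARD_AAS,
    X_INDEX,
)
from ..errors import EmptyInputError, ProfileMismatchError, UnknownSymbolError


def one_hot_aa(aa: str) -> np.ndarray:
    """Encode a residue letter as a 22-element one-hot vector.

    Alphabet order: the 20 standard residues alphabetically, then X
    (index 20), then the gap symbol ``-`` (index 21).
    """
    try:
        idx = AA_INDEX[aa]
    except KeyError:
        raise UnknownSymbolError(f"unknown residue symbol {aa!r}") from None
    vec = np.zeros(N_SYMBOLS, dtype=float)
    vec[idx] = 1.0
    return vec


@dataclass
class ProfileColumn:
    """One sequence-profile position: log-odds, frequencies, information."""

    log_odds: np.ndarray      # 20 reals, alphabetical order
    frequencies: np.ndarray   # 20 reals in [0,1], sum ~ 1 (or all-zero row)
    info_content: float

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        s = self.frequencies.sum()
        if s > 0 and abs(s - 1.0) > 1e-6:
            raise ProfileMismatchError(
                f"profile frequencies sum to {s}, expected 1"
            )


def _parse_pssm_row(parts: list[str]) -> tuple[str, np.ndarray, np.ndarray, float]:
    aa = parts[1]
    scores = np.array([float(x) for x in parts[2:22]])
    pcts = np.array([float(x) for x in parts[22:42]])
    info = float(parts[42]) if len(parts) > 42 else 0.0
    return aa, scores, pcts, info


def read_pssm(path: str, sequence: str | None = None) -> list[ProfileColumn]:
    """Read a PSI-BLAST ASCII PSSM file into per-position profile columns.

    Percentages are converted to frequencies in [0,1].  If ``sequence`` is
    given, a row-count (or residue letter) disagreement raises
    :class:`ProfileMismatchError`.
    """
    columns: list[ProfileColumn] = []
    letters: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 42 or not parts[0].lstrip("-").isdigit():
                continue
            aa, scores, pcts, info = _parse_pssm_row(parts)
            log_odds = np.zeros(20)
            freqs = np.zeros(20)
            log_odds[PSIBLAST_TO_ALPHA] = scores
            freqs[PSIBLAST_TO_ALPHA] = pcts / 100.0
            total = freqs.sum()
            if total > 0:
                freqs = freqs / total
            letters.append(aa)
            columns.append(ProfileColumn(log_odds, freqs, info))
    if not columns:
        raise ProfileMismatchError(f"{path}: no profile rows found")
    if sequence is not None:
        if len(columns) != len(sequence):
            raise ProfileMismatchError(
                f"{path}: {len(columns)} profile rows for a "
                f"{len(sequence)}-residue chain"
            )
        for k, (file_aa, chain_aa) in enumerate(zip(letters, sequence)):
            if chain_aa in STANDARD_AAS and file_aa != chain_aa:
                raise ProfileMismatchError(
                    f"{path}: residue mismatch at position {k}: "
                    f"file {file_aa!r} vs chain {chain_aa!r}"
                )
    return columns


def write_pssm(path: str, sequence: str,
               log_odds: np.ndarray, percentages: np.ndarray,
               info: np.ndarray) -> None:
    """Write integer profile rows in the PSI-BLAST ASCII PSSM dialect.

    ``log_odds`` and ``percentages`` are (L, 20) integer arrays in the
    package's alphabetical order; they are emitted in PSI-BLAST column
    order so that :func:`read_pssm` round-trips them.
    """
    header_aas = "   ".join(PSIBLAST_ORDER)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write("            " + header_aas + "   " + header_aas + "\n")
        for k, aa in enumerate(sequence):
            lo = np.asarray(log_odds[k])[PSIBLAST_TO_ALPHA]
            pc = np.asarray(percentages[k])[PSIBLAST_TO_ALPHA]
            row = f"{k + 1:5d} {aa} "
            row += " ".join(f"{int(v):3d}" for v in lo)
            row += "  "
            row += " ".join(f"{int(v):3d}" for v in pc)
            row += f"  {float(info[k]):5.2f} 0.00\n"
            fh.write(row)
        fh.write("\n")


_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum_row(aa: str) -> np.ndarray:
    """BLOSUM62 substitution scores of ``aa`` against the 20 standard
    residues, in alphabetical order; zeros for X/gap."""
    if aa not in AA_INDEX:
        raise UnknownSymbolError(f"unknown residue symbol {aa!r}")
    if AA_INDEX[aa] >= 20:
        return np.zeros(20)
    return np.array([_BLOSUM62[aa][b] for b in STANDARD_AAS], dtype=float)


def pseudo_profile(sequence: str) -> list[ProfileColumn]:
    """Deterministic substitution-matrix fallback profile.

    Log-odds are the BLOSUM62 row of each residue; frequencies are the
    background-weighted softmax ``f_b ~ q_b * 2**s_b`` of that row, which
    reduces to the background distribution for X.
    """
    if not sequence:
        raise EmptyInputError("empty sequence")
    columns = []
    for aa in sequence:
        row = blosum_row(aa)
        weights = BACKGROUND_FREQS * np.exp2(row)
        freqs = weights / weights.sum()
        info = float(np.sum(freqs * np.log2(freqs / BACKGROUND_FREQS)))
        columns.append(ProfileColumn(row, freqs, max(info, 0.0)))
    return columns


def conservation(profile: ProfileColumn) -> float:
    """Normalised-entropy conservation of a profile column.

    Returns ``1 - H(f)/log(20)`` in [0, 1]; 1 means a fully conserved
    position, 0 a uniform one.
    """
    f = np.asarray(profile.frequencies, dtype=float)
    total = f.sum()
    if total <= 0:
        raise EmptyInputError("all-zero frequency column")
    f = f / total
    nz = f[f > 0]
    entropy = float(-(nz * np.log(nz)).sum())
    return 1.0 - entropy / np.log(20.0)
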