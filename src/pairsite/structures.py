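"""Two-chain complex data model, PDB/FASTA loading and contact labelling.

A complex is a :class:`ProteinPair` of two ordered residue lists.  In
structural mode every residue carries its heavy (non-hydrogen) atoms; two
cross-chain residues are labelled as interacting when the minimum distance
between any of their heavy atoms is strictly below 6.0 Angstrom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import SeqIO

from ._tables import AA_INDEX, aa_from_resname
from .errors import (
    EmptyChainError,
    EmptyInputError,
    MissingChainError,
    UnknownSymbolError,
    UnsupportedModeError,
)

#: Default heavy-atom distance threshold (Angstrom) defining a contact.
CONTACT_THRESHOLD = 6.0


@dataclass
class Residue:
    """One residue of a chain.

    ``seq_index`` is the gap-free positional index used everywhere inside
    the package (sliding windows, contact matrices); ``res_number`` keeps
    the author numbering from the source file for reporting.
    """

    chain_id: str
    seq_index: int
    res_number: int
    aa: str
    atom_names: list[str] = field(default_factory=list)
    heavy_atoms: np.ndarray = field(
        default_factory=lambda: np.zeros((0, 3), dtype=float)
    )
    elements: list[str] = field(default_factory=list)
    insertion_code: str = ""

    @property
    def ca(self) -> np.ndarray | None:
        """C-alpha coordinate, or None if unresolved."""
        try:
            return self.heavy_atoms[self.atom_names.index("CA")]
        except ValueError:
            return None

    def atom(self, name: str) -> np.ndarray | None:
        try:
            return self.heavy_atoms[self.atom_names.index(name)]
        except ValueError:
            return None

    @property
    def resolved(self) -> bool:
        return len(self.atom_names) > 0


@dataclass
class ProteinPair:
    """Two chains forming one complex instance."""

    complex_id: str
    chain_a: list[Residue]
    chain_b: list[Residue]
    mode: str = "structural"  # "structural" | "sequence"

    def __post_init__(self) -> None:
        if not self.chain_a or not self.chain_b:
            raise EmptyChainError(
                f"{self.complex_id}: both chains must be non-empty"
            )

    def chain(self, which: str) -> list[Residue]:
        return self.chain_a if which == "a" else self.chain_b

    def sequence(self, which: str) -> str:
        return "".join(r.aa for r in self.chain(which))

    def swapped(self) -> "ProteinPair":
        """Same complex with the chain roles exchanged."""
        return ProteinPair(
            complex_id=self.complex_id,
            chain_a=self.chain_b,
            chain_b=self.chain_a,
            mode=self.mode,
        )


@dataclass
class ContactMap:
    """Boolean cross-chain contact labels plus a missing-data mask."""

    complex_id: str
    labels: np.ndarray  # bool, shape (len A, len B)
    threshold: float
    missing: np.ndarray | None = None  # bool, True where a residue had no atoms

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    def transposed(self) -> "ContactMap":
        return ContactMap(
            complex_id=self.complex_id,
            labels=self.labels.T.copy(),
            threshold=self.threshold,
            missing=None if self.missing is None else self.missing.T.copy(),
        )


def _extract_chain(model: gemmi.Model, chain_id: str, path: str) -> list[Residue]:
    chain = model.find_chain(chain_id)
    if chain is None:
        raise MissingChainError(f"{path}: chain {chain_id!r} not found")
    residues: list[Residue] = []
    for res in chain:
        if res.is_water():
            continue
        info = gemmi.find_tabulated_residue(res.name)
        is_aa = info.is_amino_acid() if info is not None else False
        # ATOM records are polymer residues (unknown names become X);
        # HETATM records are kept only for tabulated amino acids like MSE.
        if res.het_flag == "H" and not is_aa:
            continue  # hetero ligand
        names: list[str] = []
        coords: list[list[float]] = []
        elements: list[str] = []
        occup: dict[str, float] = {}
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            # altloc policy: keep the highest-occupancy conformer per atom
            # name; ties broken in favour of the first seen (altloc order).
            if atom.name in occup and atom.occ <= occup[atom.name]:
                continue
            if atom.name in occup:
                k = names.index(atom.name)
                coords[k] = [atom.pos.x, atom.pos.y, atom.pos.z]
                elements[k] = atom.element.name.upper()
            else:
                names.append(atom.name)
                coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
                elements.append(atom.element.name.upper())
            occup[atom.name] = atom.occ
        residues.append(
            Residue(
                chain_id=chain_id,
                seq_index=len(residues),
                res_number=res.seqid.num,
                aa=aa_from_resname(res.name),
                atom_names=names,
                heavy_atoms=np.asarray(coords, dtype=float).reshape(-1, 3),
                elements=elements,
                insertion_code=(res.seqid.icode or "").strip(),
            )
        )
    if not residues:
        raise EmptyChainError(f"{path}: chain {chain_id!r} has no protein residues")
    return residues


def load_structure(path: str, chain_a_id: str, chain_b_id: str,
                   complex_id: str | None = None) -> ProteinPair:
    """Read a two-chain complex from a PDB file.

    Only the first model is used.  Waters and non-amino-acid ligands are
    dropped; nonstandard amino acids are mapped through a fixed residue-name
    table (MSE -> M, unknown -> X).  Hydrogens are discarded and, for
    alternate conformations, only the highest-occupancy atom is kept.
    Residues are ordered by file appearance and indexed positionally.
    """
    structure = gemmi.read_structure(str(path))
    if len(structure) == 0:
        raise EmptyChainError(f"{path}: no models in file")
    model = structure[0]
    chain_a = _extract_chain(model, chain_a_id, str(path))
    chain_b = _extract_chain(model, chain_b_id, str(path))
    return ProteinPair(
        complex_id=complex_id or f"{structure.name or 'complex'}_{chain_a_id}{chain_b_id}",
        chain_a=chain_a,
        chain_b=chain_b,
        mode="structural",
    )


def _chain_from_sequence(seq: str, chain_id: str) -> list[Residue]:
    residues = []
    for k, aa in enumerate(seq.upper()):
        if aa not in AA_INDEX or aa == "-":
            raise UnknownSymbolError(f"residue letter {aa!r} at position {k}")
        residues.append(
            Residue(chain_id=chain_id, seq_index=k, res_number=k + 1, aa=aa)
        )
    return residues


def load_fasta_pair(path_a: str, path_b: str, complex_id: str = "complex") -> ProteinPair:
    """Build a sequence-only pair from two single-record FASTA files."""
    rec_a = next(SeqIO.parse(str(path_a), "fasta"))
    rec_b = next(SeqIO.parse(str(path_b), "fasta"))
    return ProteinPair(
        complex_id=complex_id,
        chain_a=_chain_from_sequence(str(rec_a.seq), "A"),
        chain_b=_chain_from_sequence(str(rec_b.seq), "B"),
        mode="sequence",
    )


def pair_from_sequences(seq_a: str, seq_b: str, complex_id: str = "complex") -> ProteinPair:
    return ProteinPair(
        complex_id=complex_id,
        chain_a=_chain_from_sequence(seq_a, "A"),
        chain_b=_chain_from_sequence(seq_b, "B"),
        mode="sequence",
    )


def compute_contacts(pair: ProteinPair, threshold: float = CONTACT_THRESHOLD) -> ContactMap:
    """Label every cross-chain residue pair by the heavy-atom distance rule.

    A pair is a contact when the minimum distance over all heavy-atom pairs
    is strictly less than ``threshold``.  Pairs in which either residue has
    no resolved atoms are labelled non-contact and flagged in ``missing``.
    """
    if pair.mode != "structural":
        raise UnsupportedModeError(
            f"{pair.complex_id}: contacts require structural mode"
        )
    na, nb = len(pair.chain_a), len(pair.chain_b)
    labels = np.zeros((na, nb), dtype=bool)
    missing = np.zeros((na, nb), dtype=bool)
    atoms_a = [r.heavy_atoms for r in pair.chain_a]
    atoms_b = [r.heavy_atoms for r in pair.chain_b]
    empty_a = np.array([a.shape[0] == 0 for a in atoms_a])
    empty_b = np.array([b.shape[0] == 0 for b in atoms_b])
    missing[empty_a, :] = True
    missing[:, empty_b] = True

    if (~empty_a).any() and (~empty_b).any():
        all_a = np.concatenate([a for a in atoms_a if a.shape[0]])
        all_b = np.concatenate([b for b in atoms_b if b.shape[0]])
        idx_a = np.concatenate([
            np.full(a.shape[0], i) for i, a in enumerate(atoms_a) if a.shape[0]
        ])
        idx_b = np.concatenate([
            np.full(b.shape[0], j) for j, b in enumerate(atoms_b) if b.shape[0]
        ])
        d2 = ((all_a[:, None, :] - all_b[None, :, :]) ** 2).sum(axis=2)
        mind2 = np.full((na, nb), np.inf)
        np.minimum.at(mind2, (idx_a[:, None], idx_b[None, :]), d2)
        labels = mind2 < threshold ** 2
    labels[missing] = False
    return ContactMap(pair.complex_id, labels, float(threshold), missing)


def write_contact_table(pair: ProteinPair, contacts: ContactMap, path: str) -> None:
    """Write contact labels as TSV: complex, chainA, resA, chainB, resB, label."""
    with open(path, "w") as fh:
        fh.write("complex_id\tchain_a\tres_a\tchain_b\tres_b\tlabel\n")
        for i, ra in enumerate(pair.chain_a):
            for j, rb in enumerate(pair.chain_b):
                fh.write(
                    f"{pair.complex_id}\t{ra.chain_id}\t{ra.res_number}\t"
                    f"{rb.chain_id}\t{rb.res_number}\t"
                    f"{int(contacts.labels[i, j])}\n"
                )


def interface_residues(contacts: ContactMap) -> tuple[np.ndarray, np.ndarray]:
    """Per-chain boolean interface masks (residue participates in >=1 contact)."""
    if contacts.labels.size == 0:
        raise EmptyInputError("empty contact map")
    return contacts.labels.any(axis=1), contacts.labels.any(axis=0)
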