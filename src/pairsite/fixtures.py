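"""Deterministic synthetic two-chain complexes, profiles and datasets.

The generator builds two poly-peptide backbones (N, CA, C, O plus a CB
pseudo side chain) from ideal internal coordinates for a helix, strand or
coil template, and rigidly places chain B crossing over chain A so that a
designated contiguous block of residues on each chain — and only that
block — falls within the 6.0 Angstrom heavy-atom contact range.  Ground
truth contact labels are always recomputed from the generated coordinates,
never hard-coded, so geometry and labels cannot drift apart.

Synthetic sequence profiles emulate evolutionary conservation: interface
residues draw concentrated (low-entropy) frequency columns, non-interface
residues draw near-uniform ones, mixed by an informativeness knob in
[0, 1] (0 = classes indistinguishable).  Profiles are quantised to integer
percentages so they round-trip losslessly through the PSI-BLAST ASCII
reader/writer.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

from ._tables import BACKGROUND_FREQS, AA_INDEX, ONE_TO_THREE, STANDARD_AAS
from .errors import InfeasibleGeometryError
from .features.profiles import ProfileColumn, write_pssm
from .structures import (
    ContactMap,
    ProteinPair,
    Residue,
    compute_contacts,
    interface_residues,
)

# Ideal backbone internal coordinates (Angstrom / degrees).
_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.5}
_OMEGA = 180.0
_PHI_PSI = {
    "helix": (-57.0, -47.0),
    "strand": (-139.0, 135.0),
    "coil": (-78.0, 149.0),
}


@dataclass
class ToyComplexSpec:
    """Recipe for one synthetic complex."""

    seed: int
    n_res_a: int = 16
    n_res_b: int = 16
    interface_width: int = 4
    geometry: str = "strand"
    feature_informativeness: float = 0.9


@dataclass
class ToyComplex:
    """A generated complex with its derived ground truth."""

    spec: ToyComplexSpec
    pair: ProteinPair
    contacts: ContactMap
    interface_a: np.ndarray
    interface_b: np.ndarray
    pdb_text: str
    profiles_a: list[ProfileColumn] = field(default_factory=list)
    profiles_b: list[ProfileColumn] = field(default_factory=list)
    profile_arrays: dict = field(default_factory=dict)

    @property
    def complex_id(self) -> str:
        return self.pair.complex_id


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of a fourth atom."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # ideal tetrahedral C-beta from the backbone frame
    b = ca - n
    cc = c - ca
    a = np.cross(b, cc)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cc + ca


def build_backbone(sequence: str, geometry: str) -> list[dict[str, np.ndarray]]:
    """Ideal-geometry backbone (N, CA, C, O [, CB]) for one chain."""
    phi, psi = _PHI_PSI[geometry]
    n_res = len(sequence)
    residues: list[dict[str, np.ndarray]] = []
    # seed atoms for the first residue
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    ang = np.radians(180.0 - _ANGLE["N-CA-C"])
    c0 = ca0 + _BOND["CA-C"] * np.array([np.cos(ang), np.sin(ang), 0.0])
    residues.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = residues[-1]
        n_i = _place_atom(prev["N"], prev["CA"], prev["C"],
                          _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca_i = _place_atom(prev["CA"], prev["C"], n_i,
                           _BOND["N-CA"], _ANGLE["C-N-CA"], _OMEGA)
        c_i = _place_atom(prev["C"], n_i, ca_i,
                          _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        residues.append({"N": n_i, "CA": ca_i, "C": c_i})
        # carbonyl O of the previous residue: anti to the next amide N
        prev["O"] = _place_atom(n_i, prev["CA"], prev["C"],
                                _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
    # last residue's O from an extrapolated N
    last = residues[-1]
    n_virt = _place_atom(last["N"], last["CA"], last["C"],
                         _BOND["C-N"], _ANGLE["CA-C-N"], psi)
    last["O"] = _place_atom(n_virt, last["CA"], last["C"],
                            _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
    for res, aa in zip(residues, sequence):
        if aa != "G":
            res["CB"] = _cb_position(res["N"], res["CA"], res["C"])
    return residues


def _align_to_x(residues: list[dict[str, np.ndarray]]) -> None:
    """Rigidly move a chain so its CA principal axis is +x, centroid at 0."""
    cas = np.array([r["CA"] for r in residues])
    centroid = cas.mean(axis=0)
    u, s, vt = np.linalg.svd(cas - centroid)
    rot = vt  # rows: principal axes
    if np.linalg.det(rot) < 0:
        rot[2] *= -1
    if (rot @ (cas[-1] - cas[0]))[0] < 0:  # chain runs along +x
        rot[0] *= -1
        rot[1] *= -1
    for res in residues:
        for name in res:
            res[name] = rot @ (res[name] - centroid)


def _rigid(residues, rot: np.ndarray, shift: np.ndarray):
    return [
        {name: rot @ xyz + shift for name, xyz in res.items()}
        for res in residues
    ]


_ATOM_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}
_ATOM_ORDER = ["N", "CA", "C", "O", "CB"]


def _to_pair(complex_id: str, seq_a: str, atoms_a, seq_b: str, atoms_b) -> ProteinPair:
    def chain(cid, seq, atom_list):
        out = []
        for k, (aa, atoms) in enumerate(zip(seq, atom_list)):
            names = [n for n in _ATOM_ORDER if n in atoms]
            out.append(Residue(
                chain_id=cid, seq_index=k, res_number=k + 1, aa=aa,
                atom_names=names,
                heavy_atoms=np.array([atoms[n] for n in names]),
                elements=[_ATOM_ELEMENTS[n] for n in names],
            ))
        return out

    return ProteinPair(complex_id, chain("A", seq_a, atoms_a),
                       chain("B", seq_b, atoms_b), mode="structural")


def _pdb_text(pair: ProteinPair) -> str:
    st = gemmi.Structure()
    st.name = pair.complex_id
    model = gemmi.Model("1")
    for chain_res in (pair.chain_a, pair.chain_b):
        chain = gemmi.Chain(chain_res[0].chain_id)
        for res in chain_res:
            g_res = gemmi.Residue()
            g_res.name = ONE_TO_THREE.get(res.aa, "UNK")
            g_res.seqid = gemmi.SeqId(res.res_number, " ")
            for name, xyz, el in zip(res.atom_names, res.heavy_atoms, res.elements):
                atom = gemmi.Atom()
                atom.name = name
                atom.element = gemmi.Element(el)
                atom.pos = gemmi.Position(*(float(round(v, 3)) for v in xyz))
                atom.occ = 1.0
                atom.b_iso = 0.0
                g_res.add_atom(atom)
            chain.add_residue(g_res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string()


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(STANDARD_AAS[k] for k in rng.integers(0, 20, size=n))


def make_toy_complex(spec: ToyComplexSpec, complex_id: str | None = None) -> ToyComplex:
    """Generate one synthetic complex realising the requested interface.

    Chain A lies along x; chain B crosses above it at height d and
    crossing angle theta, both scanned over a deterministic grid until the
    set of residues within contact range is exactly the designated block
    on each chain.  Raises :class:`InfeasibleGeometryError` when no grid
    point realises the request.
    """
    if spec.geometry not in _PHI_PSI:
        raise InfeasibleGeometryError(f"unknown geometry {spec.geometry!r}")
    if min(spec.n_res_a, spec.n_res_b) < 6:
        raise InfeasibleGeometryError("chains must have at least 6 residues")
    w = spec.interface_width
    if w < 1 or w > min(spec.n_res_a, spec.n_res_b):
        raise InfeasibleGeometryError(
            f"interface width {w} infeasible for chain lengths "
            f"{spec.n_res_a}/{spec.n_res_b}")
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    seq_a = _random_sequence(rng, spec.n_res_a)
    seq_b = _random_sequence(rng, spec.n_res_b)
    cid = complex_id or f"toy{spec.seed:05d}"

    atoms_a = build_backbone(seq_a, spec.geometry)
    _align_to_x(atoms_a)
    atoms_b0 = build_backbone(seq_b, spec.geometry)
    _align_to_x(atoms_b0)

    start_a = (spec.n_res_a - w) // 2
    start_b = (spec.n_res_b - w) // 2
    block_a = np.zeros(spec.n_res_a, dtype=bool)
    block_a[start_a:start_a + w] = True
    block_b = np.zeros(spec.n_res_b, dtype=bool)
    block_b[start_b:start_b + w] = True
    center_a = np.array([r["CA"] for r in atoms_a])[block_a].mean(axis=0)

    for roll_deg in range(0, 360, 60):
        roll = np.radians(roll_deg)
        roll_mat = np.array([
            [1.0, 0.0, 0.0],
            [0.0, np.cos(roll), -np.sin(roll)],
            [0.0, np.sin(roll), np.cos(roll)],
        ])
        for theta_deg in range(90, 14, -10):
            theta = np.radians(theta_deg)
            rot = np.array([
                [np.cos(theta), -np.sin(theta), 0.0],
                [np.sin(theta), np.cos(theta), 0.0],
                [0.0, 0.0, 1.0],
            ]) @ roll_mat
            for d in np.arange(3.5, 8.76, 0.25):
                rotated = _rigid(atoms_b0, rot, np.zeros(3))
                center_b = np.array([r["CA"] for r in rotated])[block_b].mean(axis=0)
                shift = center_a + np.array([0.0, 0.0, d]) - center_b
                atoms_b = _rigid(rotated, np.eye(3), shift)
                pair = _to_pair(cid, seq_a, atoms_a, seq_b, atoms_b)
                contacts = compute_contacts(pair)
                got_a, got_b = interface_residues(contacts)
                if np.array_equal(got_a, block_a) and np.array_equal(got_b, block_b):
                    toy = ToyComplex(
                        spec=spec, pair=pair, contacts=contacts,
                        interface_a=block_a, interface_b=block_b,
                        pdb_text=_pdb_text(pair),
                    )
                    _attach_profiles(toy, rng)
                    return toy
    raise InfeasibleGeometryError(
        f"could not realise a width-{w} interface for spec {spec}")


# ---------------------------------------------------------------------------
# Synthetic profiles
# ---------------------------------------------------------------------------

def _quantize_percent(freqs: np.ndarray) -> np.ndarray:
    """Round frequencies to integer percentages summing to exactly 100."""
    scaled = freqs * 100.0
    base = np.floor(scaled).astype(int)
    remainder = scaled - base
    deficit = 100 - int(base.sum())
    order = np.argsort(-remainder, kind="stable")
    base[order[:deficit]] += 1
    return base


def synthetic_profile_arrays(sequence: str, interface_mask: np.ndarray,
                             informativeness: float,
                             rng: np.random.Generator):
    """Integer (log-odds, percentages, info) profile rows for one chain.

    Non-interface positions draw near-uniform Dirichlet columns; interface
    positions draw, with probability ``informativeness``, a column
    concentrated on the residue's own amino acid.  At informativeness 0
    the two classes are generated identically.
    """
    n = len(sequence)
    pcts = np.zeros((n, 20), dtype=int)
    log_odds = np.zeros((n, 20), dtype=int)
    info = np.zeros(n)
    flat_alpha = np.full(20, 2.0)
    for k, aa in enumerate(sequence):
        peaked = bool(interface_mask[k]) and rng.random() < informativeness
        if peaked:
            own = AA_INDEX[aa] if AA_INDEX.get(aa, 20) < 20 else int(rng.integers(20))
            alpha = np.full(20, 0.2)
            alpha[own] = 25.0
            freqs = rng.dirichlet(alpha)
        else:
            freqs = rng.dirichlet(flat_alpha)
        pct = _quantize_percent(freqs)
        pcts[k] = pct
        f = pct / 100.0
        f_eff = np.maximum(f, 0.005)
        log_odds[k] = np.clip(
            np.round(2.0 * np.log2(f_eff / BACKGROUND_FREQS)), -10, 12
        ).astype(int)
        pos = f > 0
        info[k] = round(float(np.sum(
            f[pos] * np.log2(f[pos] / BACKGROUND_FREQS[pos]))), 2)
    info = np.maximum(info, 0.0)
    return log_odds, pcts, info


def _columns_from_arrays(log_odds, pcts, info) -> list[ProfileColumn]:
    cols = []
    for lo, pc, ic in zip(log_odds, pcts, info):
        freqs = pc / 100.0
        total = freqs.sum()
        cols.append(ProfileColumn(lo.astype(float),
                                  freqs / total if total > 0 else freqs,
                                  float(ic)))
    return cols


def _attach_profiles(toy: ToyComplex, rng: np.random.Generator) -> None:
    inf = toy.spec.feature_informativeness
    for which, mask in (("a", toy.interface_a), ("b", toy.interface_b)):
        seq = toy.pair.sequence(which)
        lo, pc, ic = synthetic_profile_arrays(seq, mask, inf, rng)
        toy.profile_arrays[which] = (lo, pc, ic)
        cols = _columns_from_arrays(lo, pc, ic)
        if which == "a":
            toy.profiles_a = cols
        else:
            toy.profiles_b = cols


def make_synthetic_profiles(toy: ToyComplex, dir_path: str) -> dict[str, str]:
    """Write the complex's profiles as PSI-BLAST ASCII PSSM files."""
    os.makedirs(dir_path, exist_ok=True)
    paths = {}
    for which in ("a", "b"):
        lo, pc, ic = toy.profile_arrays[which]
        path = os.path.join(dir_path, f"{toy.complex_id}_{which}.pssm")
        write_pssm(path, toy.pair.sequence(which), lo, pc, ic)
        paths[which] = path
    return paths


# ---------------------------------------------------------------------------
# Benchmark sets
# ---------------------------------------------------------------------------

def make_benchmark_set(n_complexes: int, seed: int,
                       informativeness: float = 0.9,
                       out_dir: str | None = None,
                       templates: tuple[str, ...] = ("strand", "coil"),
                       ) -> list[ToyComplex]:
    """A varied set of toy complexes suitable for leave-one-out runs.

    Chain lengths, interface widths and backbone templates vary
    deterministically with the seed; each complex gets an independent
    sub-seed so the set is stable under insertion/removal.  When
    ``out_dir`` is given, PDB/FASTA/PSSM files plus a JSON manifest are
    written there.
    """
    if n_complexes < 2:
        raise InfeasibleGeometryError("a benchmark needs at least 2 complexes")
    complexes = []
    for k in range(n_complexes):
        # some sampled recipes are geometrically infeasible; redraw
        # deterministically (retry counter in the spawn key) until one works
        for attempt in range(12):
            sub = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(k, attempt)))
            sub_seed = int(sub.integers(0, 2 ** 31 - 1))
            spec = ToyComplexSpec(
                seed=sub_seed,
                n_res_a=int(sub.integers(14, 23)),
                n_res_b=int(sub.integers(14, 23)),
                interface_width=int(sub.integers(3, 6)),
                geometry=templates[k % len(templates)],
                feature_informativeness=informativeness,
            )
            try:
                complexes.append(
                    make_toy_complex(spec, complex_id=f"toy{seed:03d}_{k:02d}"))
                break
            except InfeasibleGeometryError:
                continue
        else:
            raise InfeasibleGeometryError(
                f"no feasible recipe for benchmark slot {k} (seed {seed})")
    if out_dir is not None:
        write_benchmark_set(complexes, out_dir)
    return complexes


def write_benchmark_set(complexes: list[ToyComplex], out_dir: str) -> str:
    os.makedirs(out_dir, exist_ok=True)
    manifest = {"complexes": []}
    for toy in complexes:
        cid = toy.complex_id
        pdb_path = os.path.join(out_dir, f"{cid}.pdb")
        with open(pdb_path, "w") as fh:
            fh.write(toy.pdb_text)
        fasta_path = os.path.join(out_dir, f"{cid}.fasta")
        with open(fasta_path, "w") as fh:
            fh.write(f">{cid}_A\n{toy.pair.sequence('a')}\n")
            fh.write(f">{cid}_B\n{toy.pair.sequence('b')}\n")
        pssm_paths = make_synthetic_profiles(toy, out_dir)
        manifest["complexes"].append({
            "id": cid, "pdb": os.path.basename(pdb_path),
            "chain_a": "A", "chain_b": "B",
            "fasta": os.path.basename(fasta_path),
            "pssm_a": os.path.basename(pssm_paths["a"]),
            "pssm_b": os.path.basename(pssm_paths["b"]),
            "interface_width": int(toy.spec.interface_width),
            "geometry": toy.spec.geometry,
            "seed": int(toy.spec.seed),
        })
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest_path
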