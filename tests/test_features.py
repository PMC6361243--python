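"""Single-residue features: one-hot, profiles, conservation, structure."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from pairsite._tables import AA_ALPHABET, MAX_ASA, SASA_PROBE_RADIUS, STANDARD_AAS
from pairsite.errors import EmptyInputError, ProfileMismatchError, UnknownSymbolError
from pairsite.features import (
    ProfileColumn,
    accessibility,
    conservation,
    half_sphere_exposure,
    one_hot_aa,
    pseudo_profile,
    read_pssm,
    secondary_structure,
    shrake_rupley_sasa,
    write_pssm,
)
from pairsite.fixtures import build_backbone
from pairsite.structures import ProteinPair, Residue


class TestOneHot:
    @pytest.mark.parametrize("aa", list(AA_ALPHABET))
    def test_exactly_one_position_set(self, aa):
        vec = one_hot_aa(aa)
        assert vec.sum() == 1 and vec[AA_ALPHABET.index(aa)] == 1

    def test_x_at_index_20(self):
        assert one_hot_aa("X")[20] == 1

    def test_unknown_symbol(self):
        with pytest.raises(UnknownSymbolError):
            one_hot_aa("B")


class TestProfiles:
    def test_pssm_roundtrip(self, tmp_path):
        seq = "ACD"
        lo = np.arange(60).reshape(3, 20) % 13 - 6
        pct = np.zeros((3, 20), dtype=int)
        pct[:, :4] = 25
        info = np.array([0.5, 1.25, 0.0])
        path = tmp_path / "toy.pssm"
        write_pssm(str(path), seq, lo, pct, info)
        cols = read_pssm(str(path), seq)
        assert len(cols) == 3
        for k, col in enumerate(cols):
            assert np.array_equal(col.log_odds, lo[k])
            assert np.isclose(col.frequencies.sum(), 1.0)
            assert col.info_content == pytest.approx(info[k])
        # frequencies recover the percentages exactly
        assert np.array_equal((cols[0].frequencies * 100).round().astype(int),
                              pct[0])

    def test_row_count_mismatch(self, tmp_path):
        path = tmp_path / "bad.pssm"
        write_pssm(str(path), "ACDE", np.zeros((4, 20)),
                   np.full((4, 20), 5), np.zeros(4))
        with pytest.raises(ProfileMismatchError):
            read_pssm(str(path), "ACD")

    def test_pseudo_profile_deterministic_and_normalised(self):
        cols = pseudo_profile("AA")
        assert np.array_equal(cols[0].log_odds, cols[1].log_odds)
        assert np.array_equal(cols[0].frequencies, cols[1].frequencies)
        assert np.isclose(cols[0].frequencies.sum(), 1.0)

    def test_pseudo_profile_matches_substitution_matrix(self):
        # dual route: compare the W column against BLOSUM62 loaded directly
        blosum = substitution_matrices.load("BLOSUM62")
        expected = [blosum["W"][b] for b in STANDARD_AAS]
        col = pseudo_profile("W")[0]
        assert np.array_equal(col.log_odds, expected)


class TestConservation:
    def test_fully_conserved(self):
        freqs = np.zeros(20)
        freqs[3] = 1.0
        assert conservation(ProfileColumn(np.zeros(20), freqs, 0)) == \
            pytest.approx(1.0)

    def test_uniform_is_zero(self):
        col = ProfileColumn(np.zeros(20), np.full(20, 1 / 20), 0)
        assert conservation(col) == pytest.approx(0.0, abs=1e-12)

    def test_two_state_closed_form(self):
        freqs = np.zeros(20)
        freqs[0] = freqs[1] = 0.5
        expected = 1 - np.log(2) / np.log(20)  # ~0.7686
        col = ProfileColumn(np.zeros(20), freqs, 0)
        assert conservation(col) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.7686, abs=5e-5)

    def test_all_zero_rejected(self):
        with pytest.raises(EmptyInputError):
            conservation(ProfileColumn(np.zeros(20), np.zeros(20), 0))


def _ca_residue(idx, xyz, cb=None):
    names = ["CA"] + (["CB"] if cb is not None else [])
    atoms = [xyz] + ([cb] if cb is not None else [])
    return Residue("A", idx, idx + 1, "A", names,
                   np.asarray(atoms, dtype=float), ["C"] * len(names))


class TestHalfSphereExposure:
    def test_isolated_residue(self):
        up, down, flags = half_sphere_exposure([_ca_residue(0, [0, 0, 0])])
        assert up[0] == 0 and down[0] == 0

    def test_two_residues_within_radius(self):
        chain = [_ca_residue(0, [0, 0, 0]), _ca_residue(1, [11, 0, 0])]
        up, down, _ = half_sphere_exposure(chain)
        assert (up + down).tolist() == [1, 1]

    def test_hemisphere_split_follows_cb_direction(self):
        center = _ca_residue(0, [0, 0, 0], cb=[0, 0, 1.5])
        above = _ca_residue(1, [0, 0, 5])
        below = _ca_residue(2, [0, 0, -5])
        up, down, _ = half_sphere_exposure([center, above, below])
        assert up[0] == 1 and down[0] == 1

    def test_contact_number_matches_bruteforce(self, rng):
        coords = rng.normal(scale=8, size=(25, 3))
        chain = [_ca_residue(k, c) for k, c in enumerate(coords)]
        up, down, _ = half_sphere_exposure(chain)
        for i in range(25):
            expected = sum(
                1 for j in range(25)
                if j != i and np.linalg.norm(coords[j] - coords[i]) < 12.0
            )
            assert up[i] + down[i] == expected


def _chain_from_backbone(sequence, geometry):
    residues = []
    for k, (aa, atoms) in enumerate(zip(sequence,
                                        build_backbone(sequence, geometry))):
        names = list(atoms)
        residues.append(Residue(
            "A", k, k + 1, aa, names,
            np.array([atoms[n] for n in names]),
            ["N" if n == "N" else "O" if n == "O" else "C" for n in names]))
    return residues


class TestSecondaryStructure:
    def test_ideal_helix_interior_is_H(self):
        chain = _chain_from_backbone("A" * 14, "helix")
        classes = secondary_structure(chain)
        assert all(c == "H" for c in classes[4:10])

    def test_extended_chain_has_no_helix(self):
        chain = _chain_from_backbone("A" * 14, "strand")
        assert "H" not in secondary_structure(chain)

    def test_single_residue_unassigned(self):
        chain = _chain_from_backbone("A", "helix")
        assert secondary_structure(chain) == ["-"]


class TestAccessibility:
    def test_lone_atom_closed_form(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), ["C"])
        radius = 1.70 + SASA_PROBE_RADIUS
        assert area[0] == pytest.approx(4 * np.pi * radius ** 2)

    def test_isolated_residue_fully_exposed(self):
        res = Residue("A", 0, 1, "G", ["CA"], np.zeros((1, 3)), ["C"])
        other = Residue("B", 0, 1, "G", ["CA"],
                        np.array([[50.0, 0, 0]]), ["C"])
        pair = ProteinPair("t", [res], [other])
        rel, flags = accessibility(pair, "a")
        # one bare C atom offers ~150 A^2 against glycine's 104 A^2 maximum
        assert rel[0] == pytest.approx(1.0)
        assert not flags[0]

    def test_caged_residue_buried(self):
        # surround a residue with a tight cage of atoms
        phi = np.arccos(np.linspace(-1, 1, 80))
        theta = np.pi * (1 + 5 ** 0.5) * np.arange(80)
        cage = 4.0 * np.stack([
            np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi),
            np.cos(phi)], axis=1)
        res = Residue("A", 0, 1, "G", ["CA"], np.zeros((1, 3)), ["C"])
        cage_res = Residue("A", 1, 2, "G",
                           [f"C{k}" for k in range(80)], cage, ["C"] * 80)
        other = Residue("B", 0, 1, "G", ["CA"],
                        np.array([[90.0, 0, 0]]), ["C"])
        pair = ProteinPair("t", [res, cage_res], [other])
        rel, _ = accessibility(pair, "a")
        assert rel[0] < 0.05

    def test_unresolved_residue_flagged_zero(self):
        res = Residue("A", 0, 1, "G")
        other = Residue("B", 0, 1, "G", ["CA"], np.zeros((1, 3)), ["C"])
        rel, flags = accessibility(ProteinPair("t", [res], [other]), "a")
        assert rel[0] == 0.0 and flags[0]
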