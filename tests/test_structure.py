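"""Structure parsing, contact maps, and the atomic descriptor."""

import numpy as np
import pytest

from screenkit import chemdata as chem
from screenkit.structure import (read_structure, contact_map,
                                 atomic_descriptor, build_graph, residue_sasa)
from screenkit.synthetic import GeneratorConfig, generate_enzyme, _write_pdb
from screenkit.types import Atom, EnzymeRecord


def _linear_record(ca_positions, b=50.0):
    """Residues strung along the x-axis at the given coordinates."""
    n = len(ca_positions)
    atoms = [[Atom("C", "CA", (float(x), 0.0, 0.0), b, False)]
             for x in ca_positions]
    return EnzymeRecord(
        id="toy_A", sequence="G" * n,
        residue_numbers=[str(i + 1) for i in range(n)],
        ca_coords=np.array([[x, 0.0, 0.0] for x in ca_positions]),
        atoms=atoms)


@pytest.fixture(scope="module")
def enzyme_and_pdb(tmp_path_factory):
    cfg = GeneratorConfig(n_enzymes=1, residues_per_enzyme=25,
                          catalytic_per_enzyme=3, seed=5)
    rng = np.random.default_rng(5)
    record, profiles, embedding = generate_enzyme(cfg, rng, "SYN_A", 1)
    path = tmp_path_factory.mktemp("pdb") / "SYN.pdb"
    _write_pdb(record, path)
    return record, profiles, embedding, path


class TestReadStructure:
    def test_round_trip_matches_generator(self, enzyme_and_pdb):
        record, _, _, path = enzyme_and_pdb
        reread = read_structure(path, "A")
        assert reread.n_residues == record.n_residues
        assert reread.sequence == record.sequence
        np.testing.assert_allclose(reread.ca_coords, record.ca_coords,
                                   atol=5e-4)

    def test_missing_chain_names_available_chains(self, enzyme_and_pdb):
        *_, path = enzyme_and_pdb
        with pytest.raises(ValueError, match="available chains: A"):
            read_structure(path, "B")

    def test_residue_without_ca_is_dropped_with_warning(self, tmp_path):
        pdb = tmp_path / "noca.pdb"
        pdb.write_text(
            "ATOM      1  N   GLY A   1       0.000   1.400   0.000"
            "  1.00 20.00           N\n"
            "ATOM      2  CA  GLY A   1       0.000   0.000   0.000"
            "  1.00 20.00           C\n"
            "ATOM      3  N   ALA A   2       3.800   1.400   0.000"
            "  1.00 20.00           N\n"
            "ATOM      4  CA  ALA A   3       7.600   0.000   0.000"
            "  1.00 20.00           C\n"
            "END\n")
        with pytest.warns(UserWarning, match="lacks a CA"):
            record = read_structure(pdb, "A")
        assert record.n_residues == 2
        assert record.residue_numbers == ["1", "3"]

    def test_waters_and_hydrogens_are_excluded(self, tmp_path):
        base = (
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000"
            "  1.00 20.00           C\n"
            "ATOM      2  CA  ALA A   2       3.800   0.000   0.000"
            "  1.00 20.00           C\n")
        extra = (
            "ATOM      3  HA  ALA A   2       3.900   1.000   0.000"
            "  1.00 20.00           H\n"
            "HETATM    4  O   HOH A 101      10.000  10.000  10.000"
            "  1.00 30.00           O\n")
        clean, dirty = tmp_path / "clean.pdb", tmp_path / "dirty.pdb"
        clean.write_text(base + "END\n")
        dirty.write_text(base + extra + "END\n")
        a, b = read_structure(clean, "A"), read_structure(dirty, "A")
        assert a.sequence == b.sequence
        np.testing.assert_array_equal(a.ca_coords, b.ca_coords)
        assert [len(r) for r in a.atoms] == [len(r) for r in b.atoms]


class TestContactMap:
    def test_collinear_chain_cutoff_10(self):
        rec = _linear_record([0.0, 6.0, 12.0])
        a = contact_map(rec, cutoff=10.0)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        np.testing.assert_array_equal(a, expected)

    def test_tiny_cutoff_gives_empty_graph(self, small_dataset):
        record = small_dataset[0][0]
        a = contact_map(record, cutoff=0.1)
        assert a.sum() == 0

    def test_matches_brute_force_pairs(self, rng):
        coords = rng.normal(scale=8.0, size=(50, 3))
        rec = _linear_record(range(50))
        rec.ca_coords = coords
        a = contact_map(rec, cutoff=10.0)
        for i in range(50):
            for j in range(50):
                d = np.linalg.norm(coords[i] - coords[j])
                expected = 1.0 if (i != j and d <= 10.0) else 0.0
                assert a[i, j] == expected

    def test_monotone_in_cutoff(self, small_dataset):
        record = small_dataset[0][0]
        a_small = contact_map(record, cutoff=6.0)
        a_big = contact_map(record, cutoff=12.0)
        assert ((a_small == 1) <= (a_big == 1)).all()

    def test_nonfinite_coordinates_rejected(self):
        rec = _linear_record([0.0, 6.0])
        rec.ca_coords[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            contact_map(rec, 10.0)


class TestAtomicDescriptor:
    def test_glycine_backbone_one_hot(self):
        atoms = [[Atom("N", "N", (0, 1.4, 0), 10.0, False),
                  Atom("C", "CA", (0, 0, 0), 10.0, False),
                  Atom("C", "C", (1.2, 0, 0), 10.0, False),
                  Atom("O", "O", (2.0, 1.0, 0), 10.0, False)]]
        rec = EnzymeRecord(id="g", sequence="G", residue_numbers=["1"],
                           ca_coords=np.zeros((1, 3)), atoms=atoms)
        x = atomic_descriptor(rec, np.array([0.0]))
        np.testing.assert_allclose(x[0, :5], [0.5, 0.25, 0.25, 0.0, 0.0])
        assert x[0, 7] == 0.0  # no side-chain atoms

    def test_all_carbon_toy_residue(self):
        atoms = [[Atom("C", "CA", (0, 0, 0), 20.0, False),
                  Atom("C", "CB", (1, 0, 0), 20.0, True)]]
        rec = EnzymeRecord(id="c", sequence="A", residue_numbers=["1"],
                           ca_coords=np.zeros((1, 3)), atoms=atoms)
        x = atomic_descriptor(rec, np.array([0.0]))
        np.testing.assert_allclose(x[0, :5], [1, 0, 0, 0, 0])
        assert x[0, 5] == pytest.approx(chem.ATOMIC_MASS["C"])

    def test_matches_brute_force_averaging(self, enzyme_and_pdb):
        record, *_ = enzyme_and_pdb
        sasa = residue_sasa(record)
        x = atomic_descriptor(record, sasa)
        assert x.shape == (record.n_residues, 14)
        for i, res_atoms in enumerate(record.atoms):
            res3 = chem.AA1_TO_3[record.sequence[i]]
            masses = [chem.ATOMIC_MASS.get(a.element, chem.DEFAULT_MASS)
                      for a in res_atoms]
            assert x[i, 5] == pytest.approx(np.mean(masses))
            assert x[i, 6] == pytest.approx(
                np.mean([a.b_factor for a in res_atoms]))
            assert x[i, 8] == pytest.approx(np.mean(
                [chem.hydrogen_count(res3, a.name) for a in res_atoms]))
            assert x[i, 12] == pytest.approx(sasa[i])
        assert (x[:, 13] == 0).all()  # reserved channel

    def test_invariant_to_atom_order(self, enzyme_and_pdb, rng):
        record, *_ = enzyme_and_pdb
        sasa = residue_sasa(record)
        shuffled = EnzymeRecord(
            id=record.id, sequence=record.sequence,
            residue_numbers=record.residue_numbers,
            ca_coords=record.ca_coords,
            atoms=[[res[k] for k in rng.permutation(len(res))]
                   for res in record.atoms],
            catalytic_mask=record.catalytic_mask)
        np.testing.assert_allclose(atomic_descriptor(record, sasa),
                                   atomic_descriptor(shuffled, sasa))

    def test_sasa_length_mismatch_rejected(self, enzyme_and_pdb):
        record, *_ = enzyme_and_pdb
        with pytest.raises(ValueError, match="sasa"):
            atomic_descriptor(record, np.zeros(record.n_residues + 1))


class TestBuildGraph:
    def test_output_satisfies_invariants_and_theta(self, enzyme_and_pdb):
        record, profiles, embedding, _ = enzyme_and_pdb
        g = build_graph(record, profiles, embedding)
        g.validate()
        assert g.gcn_input.shape[1] == 64

    def test_missing_embedding_is_zero_filled_and_flagged(self, enzyme_and_pdb):
        record, profiles, _, _ = enzyme_and_pdb
        g = build_graph(record, profiles, embedding=None)
        assert g.embedding_missing
        assert (g.x_g == 0).all()

    def test_profile_row_mismatch_identifies_source(self, enzyme_and_pdb):
        from screenkit.types import ProfileSet
        record, profiles, embedding, _ = enzyme_and_pdb
        bad = ProfileSet(pssm=np.vstack([profiles.pssm, profiles.pssm[:1]]),
                         hmm=np.vstack([profiles.hmm, profiles.hmm[:1]]))
        with pytest.raises(ValueError, match="profiles have"):
            build_graph(record, bad, embedding)

    def test_graph_round_trips_through_npz(self, enzyme_and_pdb, tmp_path):
        record, profiles, embedding, _ = enzyme_and_pdb
        g = build_graph(record, profiles, embedding)
        g.save(tmp_path / "g.npz")
        g2 = type(g).load(tmp_path / "g.npz")
        np.testing.assert_array_equal(g.adjacency, g2.adjacency)
        np.testing.assert_array_equal(g.x_a, g2.x_a)
        assert g2.ec_class == g.ec_class and g2.id == g.id
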