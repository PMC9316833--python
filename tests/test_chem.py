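"""Molecular data model: parsing, topology, geometry, atom classes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import floyd_warshall
from ht6qsar import chem

METHANE_SDF = """methane
  hand-built

  5  4  0  0  0  0  0  0  0  0999 V2000
    0.0000    0.0000    0.0000 C   0  0
    0.6294    0.6294    0.6294 H   0  0
    0.6294   -0.6294   -0.6294 H   0  0
   -0.6294    0.6294   -0.6294 H   0  0
   -0.6294   -0.6294    0.6294 H   0  0
  1  2  1  0
  1  3  1  0
  1  4  1  0
  1  5  1  0
M  END
>  <PARTIAL_CHARGES>
-0.2 0.05 0.05 0.05 0.05

$$$$
"""


class TestParseMolecule:
    def test_sdf_charges_pass_through(self):
        rec = chem.parse_molecule(METHANE_SDF, charge_source="from-file")
        assert rec.n_atoms == 5
        charges = [a.partial_charge for a in rec.atoms]
        assert charges == [-0.2, 0.05, 0.05, 0.05, 0.05]
        assert rec.charge_origin == "file"

    def test_thioanisole_atom_count_after_h_addition(self):
        rec = chem.parse_molecule("c1ccccc1SC")
        assert rec.n_atoms == 16

    def test_fused_sulfone_thiophene_ligand_sulfur_environments(self):
        # the most potent molecule of the modelled dataset: a piperazinyl
        # benzothiophene bearing a phenylsulfonyl group
        smiles = "C1CNCCN1c(ccc2)c(c23)scc3S(=O)(=O)c4ccccc4"
        rec = chem.parse_molecule(smiles)
        sulfurs = [a for a in rec.atoms if a.element == "S"]
        assert len(sulfurs) == 2
        n_sulfone = sum(1 for s in sulfurs
                        if sum(1 for j in rec.heavy_neighbors(s.index)
                               if rec.atoms[j].element == "O") == 2)
        n_thioether = sum(1 for s in sulfurs if s.in_ring)
        assert n_sulfone == 1 and n_thioether == 1

    def test_unparseable_smiles_raises_named_error(self):
        with pytest.raises(chem.ParseError, match="bad_smiles"):
            chem.parse_molecule("C1CC", mol_id="bad_smiles")

    def test_missing_charges_under_from_file_policy(self):
        with pytest.raises(chem.ChargeSourceError):
            chem.parse_molecule("CCO", charge_source="from-file")

    def test_gasteiger_charges_of_neutral_molecule_sum_to_zero(self):
        for smiles in ("CCO", "c1ccccc1", "CC(=O)NC"):
            rec = chem.parse_molecule(smiles, charge_source="gasteiger")
            total = sum(a.partial_charge for a in rec.atoms)
            assert abs(total) < 0.05

    def test_embedding_is_deterministic(self):
        a = chem.parse_molecule("CCOC(=O)c1ccccc1")
        b = chem.parse_molecule("CCOC(=O)c1ccccc1")
        np.testing.assert_array_equal(a.coords_array(), b.coords_array())


class TestMoleculeRecordInvariants:
    def test_pki_derived_from_ki(self):
        rec = chem.parse_molecule("CCO", mol_id="x", ki_nM=1.0)
        assert rec.pki == pytest.approx(9.0)

    def test_inconsistent_pki_rejected(self, toy):
        import dataclasses
        with pytest.raises(ValueError, match="inconsistent"):
            dataclasses.replace(toy["methane"], ki_nM=1.0, pki=5.0)

    def test_bond_endpoints_validated(self, toy):
        import dataclasses
        with pytest.raises(ValueError, match="bond"):
            dataclasses.replace(toy["methane"], bonds=[(0, 99, 1.0)])


class TestBondDistanceMatrix:
    def test_ethane_cc_distance(self, toy):
        rec = toy["ethane"]
        d = chem.bond_distance_matrix(rec)
        assert d[0, 1] == 1

    def test_benzene_para_distance(self, toy):
        d = chem.bond_distance_matrix(toy["benzene"])
        assert d[0, 3] == 3

    def test_thioanisole_sulfur_to_para_carbon(self, toy):
        rec = toy["thioanisole"]
        s = next(a.index for a in rec.atoms if a.element == "S")
        # ring atom indices 0..5; S sits on ring atom 0, para carbon is 3
        assert chem.bond_distance_matrix(rec)[s, 3] == 4

    def test_matches_floyd_warshall_on_all_fixtures(self, toy_molecules):
        for rec in toy_molecules:
            fast = chem.bond_distance_matrix(rec)
            slow = np.array(floyd_warshall(rec))
            np.testing.assert_array_equal(fast, slow)

    def test_disconnected_graph_gets_infinite_sentinel(self, toy):
        import dataclasses
        rec = dataclasses.replace(toy["ethane"], bonds=[
            b for b in toy["ethane"].bonds if set(b[:2]) != {0, 1}])
        d = chem.bond_distance_matrix(rec)
        assert np.isinf(d[0, 1])


class TestCenterOfMass:
    def test_single_and_symmetric_pairs(self, toy):
        import dataclasses
        one = dataclasses.replace(
            toy["methane"],
            atoms=[dataclasses.replace(toy["methane"].atoms[0],
                                       coords=np.array([1.0, 2.0, 3.0]))],
            bonds=[])
        np.testing.assert_allclose(chem.center_of_mass(one), [1, 2, 3])

    def test_methane_com_at_carbon(self, toy):
        assert np.linalg.norm(chem.center_of_mass(toy["methane"])) < 0.01

    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=3))
    def test_translation_equivariance(self, v):
        rec = chem.parse_molecule("CC(=O)O")
        shifted = rec.translated(v)
        err = chem.center_of_mass(shifted) - (chem.center_of_mass(rec) + np.array(v))
        assert np.linalg.norm(err) < 1e-9


class TestClassifyAtoms:
    def test_charged_hydrogen_is_not_nonpolar(self, toy):
        rec = toy["phenol"]
        flags = chem.classify_atoms(rec)
        oh_h = next(i for i, a in enumerate(rec.atoms)
                    if a.element == "H"
                    and rec.atoms[rec.neighbors(i)[0]].element == "O")
        assert rec.atoms[oh_h].partial_charge > 0.2
        assert not flags[oh_h].is_nonpolar_h

    def test_piperidine_nh_is_donor(self, toy):
        rec = toy["piperidine"]
        flags = chem.classify_atoms(rec)
        n = next(a.index for a in rec.atoms if a.element == "N")
        assert flags[n].is_donor

    def test_methyl_carbon_bonded_only_to_carbon_is_lipophilic(self, toy):
        rec = toy["4-ethyl-5-methylimidazole"]
        flags = chem.classify_atoms(rec)
        methyls = [a.index for a in rec.atoms
                   if a.element == "C" and a.n_attached_H == 3]
        assert methyls and all(flags[i].is_lipophilic for i in methyls)

    def test_ring_carbon_adjacent_to_nitrogen_is_not_lipophilic(self, toy):
        rec = toy["pyridine"]
        flags = chem.classify_atoms(rec)
        n = next(a.index for a in rec.atoms if a.element == "N")
        for c in rec.heavy_neighbors(n):
            assert not flags[c].is_lipophilic

    def test_flag_consistency_on_all_fixtures(self, toy_molecules):
        for rec in toy_molecules:
            for a, f in zip(rec.atoms, chem.classify_atoms(rec)):
                if f.is_ring_c:
                    assert a.element == "C" and a.in_ring
                if f.is_sp3_n:
                    assert a.element == "N" and a.hybridization == "sp3"
                if f.is_sp2_o:
                    assert a.element == "O" and a.hybridization == "sp2"
                if f.is_nonpolar_h:
                    assert a.element == "H" and abs(a.partial_charge) <= 0.2
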