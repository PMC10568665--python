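"""Fingerprint families: lengths, hashed paths, keyed and atom-pair variants."""

import numpy as np
import pytest
from rdkit import Chem

from molcarc.chemio import MoleculeRecord
from molcarc.fingerprints import (FINGERPRINT_REGISTRY, atom_pair_fingerprint,
                                  compute_fingerprint, featurize_dataset,
                                  hashed_path_fingerprint, keyed_fingerprint)

EXPECTED_LENGTHS = {
    "CDK": 1024, "CDKExt": 1024, "CDKGraph": 1024, "MACCS": 166,
    "PubChem": 881, "KR": 4860, "KRC": 4860, "AP2D": 780, "AP2DC": 780,
    "FP4": 307, "FP4C": 307, "Estate": 79,
}


def test_registry_matches_published_family_sizes():
    assert set(FINGERPRINT_REGISTRY) == set(EXPECTED_LENGTHS)
    for name, spec in FINGERPRINT_REGISTRY.items():
        assert spec.length == EXPECTED_LENGTHS[name]


@pytest.mark.parametrize("name", sorted(EXPECTED_LENGTHS))
def test_output_length_and_value_domain(name):
    mol = Chem.MolFromSmiles("O=[N+]([O-])c1ccc(Cl)cc1")
    vec = compute_fingerprint(mol, name)
    spec = FINGERPRINT_REGISTRY[name]
    assert vec.shape == (spec.length,)
    if spec.kind == "structural-count":
        assert np.all(vec >= 0) and np.allclose(vec, np.round(vec))
    else:
        assert set(np.unique(vec)) <= {0.0, 1.0}


class TestHashedPaths:
    def test_methane_sets_exactly_its_single_atom_path(self):
        # one heavy atom -> the only path is "C" -> exactly one bit
        vec = hashed_path_fingerprint(Chem.MolFromSmiles("C"), 1024, 7, "plain")
        assert vec.sum() == 1

    def test_spelling_invariance(self):
        a = compute_fingerprint(Chem.MolFromSmiles("c1ccccc1O"), "CDKExt")
        b = compute_fingerprint(Chem.MolFromSmiles("OC1=CC=CC=C1"), "CDKExt")
        assert np.array_equal(a, b)

    def test_graph_style_ignores_bond_orders(self):
        benzene = Chem.MolFromSmiles("c1ccccc1")
        cyclohexane = Chem.MolFromSmiles("C1CCCCC1")
        # identical connectivity -> identical path multisets when bond
        # orders are ignored, distinct when they are not
        g1 = hashed_path_fingerprint(benzene, 1024, 7, "graph")
        g2 = hashed_path_fingerprint(cyclohexane, 1024, 7, "graph")
        assert np.array_equal(g1, g2)
        p1 = hashed_path_fingerprint(benzene, 1024, 7, "plain")
        p2 = hashed_path_fingerprint(cyclohexane, 1024, 7, "plain")
        assert not np.array_equal(p1, p2)

    def test_extended_style_separates_ring_from_chain(self):
        # hexane vs cyclohexane share linear path strings in plain style
        # prefixes; ring annotation must separate the extended vectors
        chain = hashed_path_fingerprint(Chem.MolFromSmiles("CCCCCC"), 1024, 7,
                                        "extended")
        ring = hashed_path_fingerprint(Chem.MolFromSmiles("C1CCCCC1"), 1024, 7,
                                       "extended")
        assert not np.array_equal(chain, ring)

    def test_empty_molecule_warns_and_returns_zeros(self):
        with pytest.warns(UserWarning):
            vec = hashed_path_fingerprint(Chem.MolFromSmiles(""), 64)
        assert vec.sum() == 0


class TestKeyedFamilies:
    def test_benzene_ring_key_matches_substructure_oracle(self):
        mol = Chem.MolFromSmiles("Cc1ccccc1")
        vec = compute_fingerprint(mol, "FP4")
        names = featurize_dataset([MoleculeRecord("m", "Cc1ccccc1", 0)],
                                  "FP4").feature_names
        i = names.index("FP4_benzene_ring")
        oracle = mol.HasSubstructMatch(Chem.MolFromSmarts("c1ccccc1"))
        assert bool(vec[i]) == oracle == True

    def test_count_variant_counts_two_nitro_groups(self):
        mol = Chem.MolFromSmiles("O=[N+]([O-])c1ccccc1[N+](=O)[O-]")
        names = featurize_dataset([MoleculeRecord("m", "CCC", 0)], "KRC").feature_names
        i = names.index("KRC_nitro")
        bits = compute_fingerprint(mol, "KR")
        counts = compute_fingerprint(mol, "KRC")
        assert bits[i] == 1.0 and counts[i] == 2.0

    @pytest.mark.parametrize("bit_name,count_name", [
        ("KR", "KRC"), ("FP4", "FP4C"), ("AP2D", "AP2DC")])
    def test_indicator_of_count_variant_equals_bit_variant(self, bit_name, count_name):
        mol = Chem.MolFromSmiles("NC(=O)c1ccc(O)cc1CC(C)=O")
        bits = compute_fingerprint(mol, bit_name)
        counts = compute_fingerprint(mol, count_name)
        assert np.array_equal(bits, (counts > 0).astype(float))

    def test_empty_molecule_is_all_zeros(self):
        with pytest.warns(UserWarning):
            vec = keyed_fingerprint(Chem.MolFromSmiles(""), FINGERPRINT_REGISTRY["FP4"])
        assert vec.sum() == 0


class TestAtomPairs:
    def test_ethane_single_pair_at_distance_one(self):
        vec = atom_pair_fingerprint(Chem.MolFromSmiles("CC"))
        assert vec.sum() == 1
        assert vec[0] == 1.0  # (C, C) at distance 1 is the first position

    def test_propane_counts_by_hand_enumeration(self):
        counts = atom_pair_fingerprint(Chem.MolFromSmiles("CCC"), counting=True)
        assert counts[0] == 2.0          # two C-C pairs at distance 1
        assert counts.sum() == 3.0       # plus one C-C pair at distance 2

    def test_counting_dominates_indicator(self):
        mol = Chem.MolFromSmiles("O=[N+]([O-])c1ccc(N)cc1")
        bits = atom_pair_fingerprint(mol, counting=False)
        counts = atom_pair_fingerprint(mol, counting=True)
        assert np.all(counts >= bits)


class TestFeaturizeDataset:
    RECORDS = [MoleculeRecord("a", "c1ccccc1", 1),
               MoleculeRecord("b", "CCCO", 0),
               MoleculeRecord("c", "CC(C)N", 1)]

    def test_shape_and_row_order(self):
        fm = featurize_dataset(self.RECORDS, "MACCS")
        assert fm.shape == (3, 166)
        assert fm.molecule_ids == ["a", "b", "c"]

    def test_rows_equal_single_molecule_calls(self):
        fm = featurize_dataset(self.RECORDS, "MACCS")
        single = compute_fingerprint(self.RECORDS[0].mol(), "MACCS")
        assert np.array_equal(fm.values[0], single)

    def test_permuting_records_permutes_rows(self):
        fm = featurize_dataset(self.RECORDS, "Estate")
        fm_rev = featurize_dataset(self.RECORDS[::-1], "Estate")
        assert np.array_equal(fm.values, fm_rev.values[::-1])

    def test_deterministic_across_runs(self):
        a = featurize_dataset(self.RECORDS, "CDKExt").values
        b = featurize_dataset(self.RECORDS, "CDKExt").values
        assert np.array_equal(a, b)

    def test_csv_roundtrip(self, tmp_path):
        fm = featurize_dataset(self.RECORDS, "Estate")
        path = tmp_path / "fm.csv"
        fm.to_csv(path)
        back = type(fm).from_csv(path)
        assert np.array_equal(back.values, fm.values)
        assert back.feature_names == fm.feature_names
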