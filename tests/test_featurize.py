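"""Graph and descriptor featurization against independent chemistry oracles."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, GraphDescriptors, \
    rdMolDescriptors

import hybridqsar as hq
from hybridqsar.featurize import (EDGE_FEATURE_NAMES, FeaturizationError,
                                  N_DESCRIPTORS, N_EDGE_FEATURES,
                                  N_FINGERPRINT_BITS, N_NODE_FEATURES,
                                  N_PHYSCHEM, NODE_FEATURE_NAMES,
                                  PHYSCHEM_NAMES)


class TestVocab:
    def test_cartesian_product_plus_unknown(self):
        v = hq.build_vocab(["C", "N"], ["SP2", "SP3"])
        assert len(v) == 5
        assert v.unknown_index == 4

    def test_lookup_is_deterministic(self, vocab):
        assert vocab.lookup("C", "SP3") == vocab.lookup("C", "SP3")

    def test_out_of_vocabulary_maps_to_unknown(self, vocab):
        assert vocab.lookup("Xx", "SP") == vocab.unknown_index

    def test_distinct_hybridizations_get_distinct_ids(self, vocab):
        assert vocab.lookup("C", "SP3") != vocab.lookup("C", "SP2")

    def test_duplicate_symbols_rejected(self):
        with pytest.raises(ValueError):
            hq.build_vocab(["C", "C"], ["SP3"])

    def test_roundtrip_serialization(self, vocab):
        again = hq.AtomVocab.from_dict(vocab.to_dict())
        assert again.entries == vocab.entries


class TestGraph:
    def test_ethanol_structure_and_oxygen_features(self, vocab):
        g = hq.smiles_to_graph("CCO", vocab)
        assert g.n_nodes == 3
        assert g.edge_index.shape[1] == 4  # 2 bonds, both directions
        assert g.mol_size == 20
        mol = Chem.MolFromSmiles("CCO")
        o_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "O")
        row = dict(zip(NODE_FEATURE_NAMES, g.node_features[o_idx]))
        assert row["atomic_number"] == 8
        assert row["total_h"] == 1
        assert row["is_aromatic"] == 0 and row["in_ring"] == 0
        assert row["smallest_ring_size"] == 0
        assert row["vocab_id"] == vocab.lookup("O", "SP3")

    def test_benzene_all_aromatic_ring_of_six(self, vocab):
        g = hq.smiles_to_graph("c1ccccc1", vocab)
        assert g.n_nodes == 6 and g.edge_index.shape[1] == 12
        cols = dict(zip(NODE_FEATURE_NAMES, g.node_features.T))
        assert (cols["is_aromatic"] == 1).all()
        assert (cols["in_ring"] == 1).all()
        assert (cols["smallest_ring_size"] == 6).all()
        assert (g.node_vocab_ids == vocab.lookup("C", "SP2")).all()
        bond_codes = dict(zip(EDGE_FEATURE_NAMES, g.edge_features.T))
        assert (bond_codes["bond_type"] == 4).all()  # aromatic code
        assert (bond_codes["is_aromatic"] == 1).all()

    def test_methane_is_single_isolated_node(self, vocab):
        g = hq.smiles_to_graph("C", vocab)
        assert g.n_nodes == 1 and g.edge_index.shape[1] == 0
        row = dict(zip(NODE_FEATURE_NAMES, g.node_features[0]))
        assert row["degree"] == 0 and row["total_h"] == 4
        assert g.mol_size == 6

    def test_node_and_edge_features_match_rdkit_oracle(self, vocab, panel):
        """Per-atom / per-bond features recomputed independently from RDKit."""
        for smiles in ["CCO", "c1ccccc1", "c1ccncc1", "C[C@H](N)C(=O)O"]:
            g = hq.smiles_to_graph(smiles, vocab)
            mol = Chem.MolFromSmiles(smiles)
            Chem.AssignStereochemistry(mol, cleanIt=True, force=True)
            ring_info = mol.GetRingInfo()
            for atom in mol.GetAtoms():
                i = atom.GetIdx()
                expected = [
                    vocab.lookup(atom.GetSymbol(),
                                 str(atom.GetHybridization())),
                    atom.GetAtomicNum(), atom.GetDegree(),
                    atom.GetFormalCharge(), atom.GetTotalNumHs(),
                    int(atom.GetIsAromatic()), int(atom.IsInRing()),
                    int(atom.HasProp("_CIPCode")
                        and atom.GetProp("_CIPCode") == "R"),
                    int(atom.HasProp("_CIPCode")
                        and atom.GetProp("_CIPCode") == "S"),
                    min([len(r) for r in ring_info.AtomRings() if i in r],
                        default=0),
                    atom.GetTotalValence(),
                ]
                np.testing.assert_array_equal(g.node_features[i], expected)

    def test_chiral_flags_exclusive_and_present(self, vocab):
        g = hq.smiles_to_graph("C[C@H](N)C(=O)O", vocab)
        r_flags = g.node_features[:, 7]
        s_flags = g.node_features[:, 8]
        assert not np.any((r_flags == 1) & (s_flags == 1))
        assert (r_flags + s_flags).sum() == 1  # exactly one assigned center

    def test_edge_symmetry(self, vocab, panel):
        for smiles in panel:
            g = hq.smiles_to_graph(smiles, vocab)
            seen = {}
            for k in range(g.edge_index.shape[1]):
                i, j = g.edge_index[0, k], g.edge_index[1, k]
                seen[(i, j)] = g.edge_features[k]
            for (i, j), feats in seen.items():
                assert (j, i) in seen
                np.testing.assert_array_equal(feats, seen[(j, i)])

    def test_featurization_invariant_to_atom_ordering(self, vocab, panel):
        rng = np.random.default_rng(0)
        for smiles in panel:
            mol = Chem.MolFromSmiles(smiles)
            order = rng.permutation(mol.GetNumAtoms()).tolist()
            renum = Chem.MolToSmiles(Chem.RenumberAtoms(mol, order),
                                     canonical=False)
            g1 = hq.smiles_to_graph(smiles, vocab)
            g2 = hq.smiles_to_graph(renum, vocab)
            rows1 = sorted(map(tuple, g1.node_features))
            rows2 = sorted(map(tuple, g2.node_features))
            assert rows1 == rows2
            trip1 = sorted(
                (tuple(g1.node_features[i]), tuple(g1.node_features[j]),
                 tuple(g1.edge_features[k]))
                for k, (i, j) in enumerate(g1.edge_index.T))
            trip2 = sorted(
                (tuple(g2.node_features[i]), tuple(g2.node_features[j]),
                 tuple(g2.edge_features[k]))
                for k, (i, j) in enumerate(g2.edge_index.T))
            assert trip1 == trip2

    def test_invalid_smiles_raises(self, vocab):
        with pytest.raises(FeaturizationError):
            hq.smiles_to_graph("C1CC", vocab)


class TestMolecularSize:
    @pytest.mark.parametrize("smiles,expected", [
        ("CCO", 20), ("C", 6), ("c1ccccc1", 36), ("c1ccncc1", 37),
    ])
    def test_sum_of_heavy_atomic_numbers(self, smiles, expected):
        assert hq.molecular_size(smiles) == expected

    def test_invalid_raises(self):
        with pytest.raises(FeaturizationError):
            hq.molecular_size("not-a-molecule")


# independent oracle: descriptor name -> direct RDKit call
_ORACLE = {
    "MolWt": Descriptors.MolWt,
    "LogP": Crippen.MolLogP,
    "TPSA": rdMolDescriptors.CalcTPSA,
    "NumHDonors": Descriptors.NumHDonors,
    "NumHAcceptors": Descriptors.NumHAcceptors,
    "NumRotatableBonds": Descriptors.NumRotatableBonds,
    "NumAromaticRings": Descriptors.NumAromaticRings,
    "NumAliphaticRings": Descriptors.NumAliphaticRings,
    "NumSaturatedRings": Descriptors.NumSaturatedRings,
    "RingCount": Descriptors.RingCount,
    "FractionCSP3": Descriptors.FractionCSP3,
    "HeavyAtomCount": Descriptors.HeavyAtomCount,
    "NumStereocenters": rdMolDescriptors.CalcNumAtomStereoCenters,
    "FormalCharge": Chem.GetFormalCharge,
    "NumHeteroatoms": Descriptors.NumHeteroatoms,
    "NumValenceElectrons": Descriptors.NumValenceElectrons,
    "MolMR": Crippen.MolMR,
    "Kappa1": Descriptors.Kappa1,
    "Kappa2": Descriptors.Kappa2,
    "Kappa3": Descriptors.Kappa3,
    "BertzCT": Descriptors.BertzCT,
    "NumBridgeheadAtoms": rdMolDescriptors.CalcNumBridgeheadAtoms,
    "NumSpiroAtoms": rdMolDescriptors.CalcNumSpiroAtoms,
    "HallKierAlpha": Descriptors.HallKierAlpha,
    "Chi0v": Descriptors.Chi0v,
    "Chi1v": Descriptors.Chi1v,
    "Chi2v": Descriptors.Chi2v,
    "LabuteASA": Descriptors.LabuteASA,
    "NHOHCount": Descriptors.NHOHCount,
    "NOCount": Descriptors.NOCount,
    "NumAromaticHeterocycles": Descriptors.NumAromaticHeterocycles,
    "NumAliphaticHeterocycles": Descriptors.NumAliphaticHeterocycles,
}


class TestPhyschem:
    def test_registry_has_32_named_descriptors(self):
        assert len(PHYSCHEM_NAMES) == N_PHYSCHEM == 32
        assert len(set(PHYSCHEM_NAMES)) == 32

    def test_benzene_worked_values(self):
        v = hq.compute_physchem("c1ccccc1")
        assert v["NumAromaticRings"] == 1
        assert v["RingCount"] == 1
        assert v["HeavyAtomCount"] == 6
        assert v["FractionCSP3"] == 0.0

    def test_ethane_worked_values(self):
        v = hq.compute_physchem("CC")
        assert v["FractionCSP3"] == 1.0
        assert v["NumRotatableBonds"] == 0

    def test_methane_worked_values(self):
        v = hq.compute_physchem("C")
        assert v["FormalCharge"] == 0
        assert v["NumHeteroatoms"] == 0

    def test_counts_match_hand_computation(self):
        # pyridine-4-carboxylic acid: counts derivable by inspection
        v = hq.compute_physchem("OC(=O)c1ccncc1")
        assert v["NumAromaticRings"] == 1
        assert v["NumHeteroatoms"] == 3          # N + 2 O
        assert v["HeavyAtomCount"] == 9
        assert v["NumAromaticHeterocycles"] == 1

    def test_all_descriptors_match_oracle_on_panel(self, panel):
        assert set(_ORACLE) == set(PHYSCHEM_NAMES)
        for smiles in panel:
            mine = hq.compute_physchem(smiles)
            mol = Chem.MolFromSmiles(smiles)
            for name, fn in _ORACLE.items():
                expected = float(fn(mol))
                assert mine[name] == pytest.approx(
                    expected, rel=1e-6, abs=1e-9), (smiles, name)

    def test_invalid_smiles_raises(self):
        with pytest.raises(FeaturizationError):
            hq.compute_physchem("C1CC")


class TestFingerprint:
    def test_shape_and_bit_range(self, panel):
        for smiles in panel:
            fp = hq.compute_fingerprint(smiles)
            assert fp.shape == (N_FINGERPRINT_BITS,)
            assert set(np.unique(fp)) <= {0.0, 1.0}

    def test_deterministic(self):
        np.testing.assert_array_equal(hq.compute_fingerprint("CCO"),
                                      hq.compute_fingerprint("CCO"))

    def test_distinct_molecules_differ(self):
        assert not np.array_equal(hq.compute_fingerprint("C"),
                                  hq.compute_fingerprint("c1ccccc1"))

    def test_matches_independent_morgan_computation(self, panel):
        for smiles in panel[:8]:
            mol = Chem.MolFromSmiles(smiles)
            bv = AllChem.GetMorganFingerprintAsBitVect(mol, 2, nBits=512)
            expected = np.zeros(512)
            expected[list(bv.GetOnBits())] = 1
            np.testing.assert_array_equal(hq.compute_fingerprint(smiles),
                                          expected)


class TestDescriptorVector:
    def test_combined_length_and_layout(self):
        vec = hq.descriptor_vector("CCO")
        assert vec.shape == (N_DESCRIPTORS,)
        np.testing.assert_array_equal(vec[:512],
                                      hq.compute_fingerprint("CCO"))
        pc = hq.compute_physchem("CCO")
        np.testing.assert_allclose(
            vec[512:], [pc[n] for n in PHYSCHEM_NAMES])


class TestNormalizer:
    def test_two_point_mean_and_population_std(self):
        norm = hq.fit_normalizer(np.array([[0.0], [2.0]]))
        assert norm.means[0] == 1.0 and norm.stds[0] == 1.0

    def test_self_normalization_gives_zero_mean_unit_std(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 3, size=(50, 4))
        norm = hq.fit_normalizer(x)
        z = norm.apply(x)
        np.testing.assert_allclose(z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=0), 1, atol=1e-12)

    def test_constant_dimension_maps_to_zero(self):
        x = np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        norm = hq.fit_normalizer(x)
        z = norm.apply(np.array([9.0, 123.0]))
        assert z[1] == 0.0

    def test_mean_maps_to_zero_and_mean_plus_std_to_one(self):
        x = np.array([[0.0], [2.0], [4.0]])
        norm = hq.fit_normalizer(x)
        assert norm.apply(np.array([norm.means[0]]))[0] == 0.0
        assert norm.apply(
            np.array([norm.means[0] + norm.stds[0]]))[0] == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        norm = hq.fit_normalizer(np.zeros((3, 4)) + np.arange(4))
        with pytest.raises(ValueError):
            norm.apply(np.zeros(5))

    def test_fewer_than_two_vectors_raises(self):
        with pytest.raises(ValueError):
            hq.fit_normalizer(np.zeros((1, 4)))
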