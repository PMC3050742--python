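import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from moaclust import (
    ContinuousScaler,
    DescriptorSet,
    DescriptorVector,
    bcut_descriptors,
    circular_fingerprint,
    compute_vector,
    gcut_descriptors,
    parse_smiles,
    property_descriptors,
    similarity,
    similarity_matrix,
    tanimoto,
)

C_MASS = 12.011


def uniform_weight(w):
    def scheme(mol):
        return np.full(mol.GetNumAtoms(), w)

    return scheme


class TestPropertyDescriptors:
    def test_methane_counts(self):
        v = property_descriptors(parse_smiles("C"))
        # (alogp, mw, hba, hbd, atoms, rot, rings, aromatic rings)
        assert list(v[2:]) == [0, 0, 1, 0, 0, 0]

    def test_benzene_counts(self):
        v = property_descriptors(parse_smiles("c1ccccc1"))
        assert v[2] == 0 and v[3] == 0  # no HBA/HBD
        assert v[6] == 1 and v[7] == 1  # one ring, aromatic

    def test_ethanol_hand_computed(self):
        v = property_descriptors(parse_smiles("CCO"))
        assert v[2] == 1  # acceptor: the hydroxyl O
        assert v[3] == 1  # donor: the OH
        assert v[5] == 0  # both bonds terminal, none rotatable
        # MW incl. implicit H from the standard atomic-mass table:
        # 2*C + 6*H + O
        expected_mw = 2 * 12.011 + 6 * 1.008 + 15.999
        assert v[1] == pytest.approx(expected_mw, abs=0.01)


class TestCircularFingerprint:
    def test_invariant_to_smiles_rewriting(self):
        assert circular_fingerprint(parse_smiles("CCO")) == circular_fingerprint(
            parse_smiles("OCC")
        )

    def test_methane_has_exactly_one_feature(self):
        # every radius expansion of a lone atom collapses to one environment
        assert len(circular_fingerprint(parse_smiles("C"))) == 1

    def test_self_tanimoto_is_one(self):
        for smiles in ["C", "CCO", "c1ccccc1", "CC(=O)Nc1ccc(O)cc1"]:
            fp = circular_fingerprint(parse_smiles(smiles))
            assert tanimoto(fp, fp) == 1.0

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            circular_fingerprint(parse_smiles("C"), radius=-1)


class TestEigenDescriptors:
    def test_single_atom_is_its_weight(self):
        mol = parse_smiles("C")
        for fn in (bcut_descriptors, gcut_descriptors):
            low, high = fn(mol, ["mass"])
            assert low == pytest.approx(C_MASS, abs=1e-9)
            assert high == pytest.approx(C_MASS, abs=1e-9)

    def test_two_bonded_atoms_closed_form(self):
        mol = parse_smiles("CC")
        low, high = bcut_descriptors(mol, ["mass"])
        assert low == pytest.approx(C_MASS - 1, abs=1e-9)
        assert high == pytest.approx(C_MASS + 1, abs=1e-9)
        # for two atoms the distance matrix equals the adjacency matrix
        np.testing.assert_allclose(
            gcut_descriptors(mol, ["mass"]), bcut_descriptors(mol, ["mass"]), atol=1e-12
        )

    def test_propane_path_closed_forms(self):
        mol = parse_smiles("CCC")
        low, high = bcut_descriptors(mol, ["mass"])
        assert low == pytest.approx(C_MASS - math.sqrt(2), abs=1e-9)
        assert high == pytest.approx(C_MASS + math.sqrt(2), abs=1e-9)
        glow, ghigh = gcut_descriptors(mol, ["mass"])
        assert glow == pytest.approx(C_MASS - 2, abs=1e-9)
        assert ghigh == pytest.approx(C_MASS + 1 + math.sqrt(3), abs=1e-9)

    @pytest.mark.parametrize("smiles", ["C", "CC", "CO", "O"])
    def test_bcut_equals_gcut_up_to_two_atoms_equal_weights(self, smiles):
        mol = parse_smiles(smiles)
        w = uniform_weight(5.0)
        np.testing.assert_allclose(
            bcut_descriptors(mol, [w]), gcut_descriptors(mol, [w]), atol=1e-12
        )

    @pytest.mark.parametrize(
        "a,b", [("CCO", "OCC"), ("c1ccccc1O", "Oc1ccccc1"), ("CC(C)C", "C(C)(C)C")]
    )
    def test_permutation_invariance(self, a, b):
        ma, mb = parse_smiles(a), parse_smiles(b)
        np.testing.assert_allclose(
            bcut_descriptors(ma, ["mass"]), bcut_descriptors(mb, ["mass"]), atol=1e-9
        )
        np.testing.assert_allclose(
            gcut_descriptors(ma, ["mass"]), gcut_descriptors(mb, ["mass"]), atol=1e-9
        )

    def test_default_schemes_give_six_values(self):
        assert bcut_descriptors(parse_smiles("CCO")).shape == (6,)
        assert gcut_descriptors(parse_smiles("CCO")).shape == (6,)

    def test_multi_fragment_gcut_block_matrix(self):
        # two disconnected atoms: distance block matrix is diagonal
        low, high = gcut_descriptors(parse_smiles("[Na+].[Cl-]"), [uniform_weight(3.0)])
        assert low == pytest.approx(3.0) and high == pytest.approx(3.0)


class TestSimilarity:
    def test_tanimoto_direct_formula(self):
        a = DescriptorVector(DescriptorSet.ECFP4, fingerprint=frozenset({1, 2, 3}))
        b = DescriptorVector(DescriptorSet.ECFP4, fingerprint=frozenset({2, 3, 4}))
        assert similarity(a, b) == pytest.approx(0.5)

    def test_empty_fingerprints_are_identical(self):
        a = DescriptorVector(DescriptorSet.ECFP4, fingerprint=frozenset())
        assert similarity(a, a) == 1.0

    def test_identical_property_vectors(self):
        v = DescriptorVector(
            DescriptorSet.PROPERTY, blocks={"property": np.array([1.0, 2.0])}
        )
        other = DescriptorVector(
            DescriptorSet.PROPERTY, blocks={"property": np.array([3.0, 0.0])}
        )
        scaler = ContinuousScaler().fit([v, other])
        assert similarity(v, v, scaler) == 1.0

    def test_combined_set_is_mean_of_components(self):
        # Tanimoto 2/5 = 0.4 and property similarity 0.8 -> 0.6
        lo = DescriptorVector(
            DescriptorSet.ECFP4_PROPERTY,
            fingerprint=frozenset({9}),
            blocks={"property": np.array([0.0])},
        )
        hi = DescriptorVector(
            DescriptorSet.ECFP4_PROPERTY,
            fingerprint=frozenset({8}),
            blocks={"property": np.array([1.0])},
        )
        scaler = ContinuousScaler().fit([lo, hi])
        a = DescriptorVector(
            DescriptorSet.ECFP4_PROPERTY,
            fingerprint=frozenset({1, 2, 3}),
            blocks={"property": np.array([0.0])},
        )
        b = DescriptorVector(
            DescriptorSet.ECFP4_PROPERTY,
            fingerprint=frozenset({2, 3, 4, 5}),
            blocks={"property": np.array([0.2])},
        )
        assert similarity(a, b, scaler) == pytest.approx(0.6)

    def test_set_mismatch_rejected(self):
        a = DescriptorVector(DescriptorSet.ECFP4, fingerprint=frozenset({1}))
        b = DescriptorVector(
            DescriptorSet.PROPERTY, blocks={"property": np.array([1.0])}
        )
        with pytest.raises(ValueError, match="mismatch"):
            similarity(a, b)

    def test_out_of_range_query_clamps(self):
        train = [
            DescriptorVector(DescriptorSet.PROPERTY, blocks={"property": np.array([0.0])}),
            DescriptorVector(DescriptorSet.PROPERTY, blocks={"property": np.array([1.0])}),
        ]
        scaler = ContinuousScaler().fit(train)
        query = DescriptorVector(
            DescriptorSet.PROPERTY, blocks={"property": np.array([50.0])}
        )
        s = similarity(query, train[0], scaler)
        assert 0.0 <= s <= 1.0
        assert s == pytest.approx(0.0)  # clamps to the far end of the range

    @given(
        st.sets(st.integers(0, 40), max_size=12),
        st.sets(st.integers(0, 40), max_size=12),
    )
    def test_fingerprint_similarity_axioms(self, fa, fb):
        a = DescriptorVector(DescriptorSet.ECFP4, fingerprint=frozenset(fa))
        b = DescriptorVector(DescriptorSet.ECFP4, fingerprint=frozenset(fb))
        sab, sba = similarity(a, b), similarity(b, a)
        assert 0.0 <= sab <= 1.0
        assert sab == sba
        assert similarity(a, a) == 1.0


class TestSimilarityMatrix:
    def test_matches_pairwise_similarity(self):
        mols = {s: parse_smiles(s) for s in ["CCO", "c1ccccc1O", "CCN", "CC(=O)O"]}
        vectors = {k: compute_vector(m, DescriptorSet.GCUT_PROPERTY) for k, m in mols.items()}
        scaler = ContinuousScaler().fit(vectors.values())
        sim = similarity_matrix(vectors, scaler)
        np.testing.assert_allclose(sim.values, sim.values.T)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)
        for i, ki in enumerate(sim.ids):
            for j, kj in enumerate(sim.ids):
                assert sim.values[i, j] == pytest.approx(
                    similarity(vectors[ki], vectors[kj], scaler), abs=1e-12
                )

    def test_seven_descriptor_sets_all_computable(self):
        mol = parse_smiles("CC(=O)Nc1ccc(O)cc1")
        for set_id in DescriptorSet:
            vec = compute_vector(mol, set_id)
            assert vec.set_id == set_id
            assert vec.fingerprint is not None or vec.blocks
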