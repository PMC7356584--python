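"""CD decomposition protocol, descriptor providers, feature matrix hygiene."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

import cdscreen as cs
from cdscreen.cd_features import (
    NotACyclodextrinError,
    SystemFeaturizer,
    decompose_cyclodextrin,
    decompose_structure,
    get_provider,
    registry_names,
)
from cdscreen.chem import StructureError, parse_structure
from conftest import cyclodextrin_smiles


class TestDecomposition:
    def test_native_cds_share_methanol_fragment(self):
        for name, n in (("alphaCD", 6), ("βCD", 7), ("gammaCD", 8)):
            d = decompose_cyclodextrin(name)
            assert d.n_glucose == n
            assert Chem.CanonSmiles(d.side_chain_fragment) == Chem.CanonSmiles("CO")

    def test_hydroxypropyl_fragment_is_methoxypropanol(self):
        d = decompose_cyclodextrin("HP-βCD")
        assert d.n_glucose == 7
        frag = parse_structure(d.side_chain_fragment)
        # H-terminated 2-hydroxypropyl ether: ether O + secondary alcohol on C3 chain
        assert frag.HasSubstructMatch(Chem.MolFromSmarts("[CH3]O[CH2][CH]([CH3])[OX2H]"))

    def test_registry_covers_all_sixteen_types(self):
        assert len(registry_names()) == 16
        for name in registry_names():
            d = decompose_cyclodextrin(name)
            assert d.n_glucose in (6, 7, 8)
            assert parse_structure(d.side_chain_fragment) is not None

    @pytest.mark.parametrize("n", [6, 7, 8])
    def test_structure_decomposition_detects_macrocycle(self, n):
        d = decompose_structure(parse_structure(cyclodextrin_smiles(n)))
        assert d.n_glucose == n
        assert Chem.CanonSmiles(d.side_chain_fragment) == Chem.CanonSmiles("CO")

    def test_non_cd_structure_rejected(self):
        with pytest.raises(NotACyclodextrinError):
            decompose_cyclodextrin("c1ccccc1")


class TestProviders:
    def test_guest_vector_deterministic(self):
        prov = get_provider("minimal")
        a = cs.guest_feature_vector("CC(=O)Oc1ccccc1C(=O)O", prov, conformer_seed=7)
        b = cs.guest_feature_vector("CC(=O)Oc1ccccc1C(=O)O", prov, conformer_seed=7)
        pd.testing.assert_series_equal(a, b)

    def test_enantiomers_differ_in_a_3d_descriptor(self):
        prov = get_provider("minimal")
        r = cs.guest_feature_vector("C[C@H](N)C(=O)O", prov)
        s = cs.guest_feature_vector("C[C@@H](N)C(=O)O", prov)
        assert r["chiral_volume_sum"] != pytest.approx(s["chiral_volume_sum"], abs=1e-6)

    def test_unparseable_structure_raises(self):
        with pytest.raises(StructureError, match="parse_failure"):
            cs.guest_feature_vector("C1CC", get_provider("minimal"))

    def test_full_provider_yields_hundreds_of_descriptors(self):
        vec = cs.guest_feature_vector("c1ccccc1O", get_provider("rdkit-full"))
        assert len(vec) > 200


class TestCDVectors:
    def test_natural_cds_differ_only_in_macrocycle_size(self):
        prov = get_provider("minimal")
        va = cs.cd_feature_vector(decompose_cyclodextrin("alphaCD"), prov)
        vb = cs.cd_feature_vector(decompose_cyclodextrin("betaCD"), prov)
        assert va["n_glucose"] == 6 and vb["n_glucose"] == 7
        pd.testing.assert_series_equal(va.drop("n_glucose"), vb.drop("n_glucose"))

    def test_substituted_cd_differs_in_fragment_positions(self):
        prov = get_provider("minimal")
        vb = cs.cd_feature_vector(decompose_cyclodextrin("betaCD"), prov)
        vm = cs.cd_feature_vector(decompose_cyclodextrin("methyl-betaCD"), prov)
        assert (vb.drop(["n_glucose", "degree_of_substitution"])
                != vm.drop(["n_glucose", "degree_of_substitution"])).any()

    def test_first_element_is_glucose_count(self):
        prov = get_provider("minimal")
        v = cs.cd_feature_vector(cs.CDDecomposition(7, "CO"), prov)
        assert v.index[0] == "n_glucose" and v.iloc[0] == 7.0

    def test_system_vector_concatenates_with_namespaces(self):
        prov = get_provider("minimal")
        g = cs.guest_feature_vector("CCO", prov)
        c = cs.cd_feature_vector(decompose_cyclodextrin("betaCD"), prov)
        sys_v = cs.system_feature_vector(g, c)
        assert len(sys_v) == len(g) + len(c)
        assert sys_v.index[0].startswith("guest.") and sys_v.index[-1].startswith("cd.")

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="schema_mismatch"):
            cs.system_feature_vector(pd.Series(dtype=float), pd.Series({"x": 1.0}))


class TestCleanMatrix:
    def test_constant_and_missing_columns_dropped(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0],
                          "holey": [1.0, np.nan, 2.0]})
        cleaned, names = cs.clean_feature_matrix(m)
        assert names == ["a"]

    def test_clean_matrix_unchanged(self):
        m = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 1.0]})
        cleaned, names = cs.clean_feature_matrix(m)
        pd.testing.assert_frame_equal(cleaned, m)

    def test_all_dropped_raises(self):
        with pytest.raises(ValueError):
            cs.clean_feature_matrix(pd.DataFrame({"c": [1.0, 1.0]}))


class TestSystemFeaturizer:
    def test_schema_reused_at_transform_time(self, labeled_world):
        df, feat, X, _ = labeled_world
        pairs = list(zip(df["guest_smiles"], df["cd_key"]))[:5]
        X2 = feat.transform(pairs)
        assert list(X2.columns) == feat.feature_names_
        pd.testing.assert_frame_equal(X2, X.iloc[:5].reset_index(drop=True))

    def test_transform_before_fit_fails(self):
        with pytest.raises(AttributeError):
            SystemFeaturizer().transform([("CCO", "betaCD")])
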