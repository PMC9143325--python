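import numpy as np
import pytest

from ditptox.dataset_io import LabeledDataset, MoleculeRecord
from ditptox.featurization import (
    FeatureBlock,
    FeaturizationError,
    basic_properties,
    combine_blocks,
    compute_descriptors,
    compute_fingerprint,
    load_feature_table,
    smarts_catalog_block,
    tanimoto_matrix,
)


def _ds(*smiles_labels):
    return LabeledDataset(
        [MoleculeRecord(f"x{i}", s, l) for i, (s, l) in enumerate(smiles_labels)]
    )


class TestFingerprints:
    @pytest.mark.parametrize("family,width", [("MACCS", 166), ("PubChem", 881)])
    def test_fixed_widths(self, smiles_ds, family, width):
        fp = compute_fingerprint(smiles_ds, family)
        assert fp.matrix.shape == (len(smiles_ds), width)
        assert fp.kind == "binary"
        assert set(np.unique(fp.matrix)) <= {0.0, 1.0}

    def test_hashed_width_configurable(self, smiles_ds):
        fp = compute_fingerprint(smiles_ds, "hashed", width=256)
        assert fp.matrix.shape[1] == 256
        assert compute_fingerprint(smiles_ds, "hashed").matrix.shape[1] == 1024

    def test_same_molecule_identical_rows(self):
        ds = _ds(("CCO", 1), ("CCO", 0))
        for family in ("MACCS", "PubChem", "hashed"):
            fp = compute_fingerprint(ds, family)
            np.testing.assert_array_equal(fp.matrix[0], fp.matrix[1])

    def test_unknown_family_errors(self, smiles_ds):
        with pytest.raises(FeaturizationError, match="unknown fingerprint"):
            compute_fingerprint(smiles_ds, "nope")

    def test_determinism_across_calls(self, smiles_ds):
        a = compute_fingerprint(smiles_ds, "PubChem").matrix
        b = compute_fingerprint(smiles_ds, "PubChem").matrix
        np.testing.assert_array_equal(a, b)

    def test_pubchem_element_and_ring_bits(self):
        ds = _ds(("c1ccccc1", 1))  # benzene: 6 C, 6 H, one aromatic ring
        fp = compute_fingerprint(ds, "PubChem")
        bits = dict(zip(fp.feature_names, fp.matrix[0]))
        assert bits["el:C>=4"] == 1 and bits["el:C>=8"] == 0
        assert bits["el:H>=4"] == 1
        assert bits["ring:aromatic>=1"] == 1
        assert bits["ring:heteroaromatic>=1"] == 0
        assert bits["ring:size6:any>=1"] == 1


class TestDescriptors:
    def test_13md_structure_forced_counts(self):
        ds = _ds(("c1ccccc1", 0), ("CC", 0), ("CCO", 0))
        blk = compute_descriptors(ds, "13MD")
        col = {n: j for j, n in enumerate(blk.feature_names)}
        benzene, ethane, ethanol = blk.matrix
        assert benzene[col["nRing"]] == 1
        assert benzene[col["nHBD"]] == 0
        assert benzene[col["nHBA"]] == 0
        assert ethane[col["nRot"]] == 0
        assert ethanol[col["MW"]] == pytest.approx(46.07, abs=0.01)

    def test_13md_has_13_descriptors(self, smiles_ds):
        assert compute_descriptors(smiles_ds, "13MD").n_features == 13

    def test_13md_drop_proprietary(self, smiles_ds):
        with pytest.warns(UserWarning, match="11 descriptors"):
            blk = compute_descriptors(smiles_ds, "13MD", drop_proprietary=True)
        assert blk.n_features == 11
        assert "LogD74" not in blk.feature_names

    def test_rdmd_names_recorded(self, smiles_ds):
        blk = compute_descriptors(smiles_ds, "RDMD")
        assert blk.n_features == len(blk.feature_names) > 100
        assert "MolWt" in blk.feature_names

    def test_unknown_set_errors(self, smiles_ds):
        with pytest.raises(FeaturizationError, match="unknown descriptor"):
            compute_descriptors(smiles_ds, "XMD")


class TestLoadFeatureTable:
    def test_reorders_to_dataset(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,f1,f2\nb,1,0\na,0,1\n")
        blk = load_feature_table(p, "binary", "EXT", row_ids=["a", "b"])
        assert blk.row_ids == ["a", "b"]
        np.testing.assert_array_equal(blk.matrix, [[0, 1], [1, 0]])

    def test_missing_id_errors(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,f1\na,1\n")
        with pytest.raises(FeaturizationError, match="missing molecule id"):
            load_feature_table(p, "binary", "EXT", row_ids=["a", "zz"])

    def test_non_binary_value_errors(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("id,f1\na,2\n")
        with pytest.raises(FeaturizationError, match="non-binary"):
            load_feature_table(p, "binary", "EXT")


class TestCombineBlocks:
    def _block(self, name, d, ids=("a", "b"), kind="continuous"):
        rng = np.random.default_rng(abs(hash(name)) % 2**31)
        m = rng.random((len(ids), d))
        if kind == "binary":
            m = (m > 0.5).astype(float)
        return FeatureBlock(name, kind, m, [f"f{j}" for j in range(d)], list(ids))

    def test_column_count_sums(self):
        out = combine_blocks([self._block("A", 3), self._block("B", 5)])
        assert out.n_features == 8
        assert len(set(out.feature_names)) == 8

    def test_single_block_identity(self):
        b = self._block("A", 3)
        assert combine_blocks([b]) is b

    def test_rows_aligned_by_id_not_position(self):
        a = self._block("A", 2, ids=("a", "b"))
        b = self._block("B", 2, ids=("b", "a"))
        out = combine_blocks([a, b])
        assert out.row_ids == ["a", "b"]
        np.testing.assert_array_equal(out.matrix[:, 2:], b.matrix[::-1])

    def test_duplicate_names_error(self):
        with pytest.raises(FeaturizationError, match="duplicate block"):
            combine_blocks([self._block("A", 2), self._block("A", 2)])

    def test_mixed_kind_recorded_per_column(self):
        out = combine_blocks(
            [self._block("A", 2, kind="binary"), self._block("B", 3)]
        )
        assert out.kind == "mixed"
        assert out.column_kinds == ["binary"] * 2 + ["continuous"] * 3

    def test_real_descriptor_fingerprint_widths_sum(self, smiles_ds):
        rdmd = compute_descriptors(smiles_ds, "RDMD")
        pub = compute_fingerprint(smiles_ds, "PubChem")
        out = combine_blocks([rdmd, pub])
        assert out.n_features == rdmd.n_features + 881


class TestTanimoto:
    def _bin(self, rows):
        m = np.array(rows, dtype=float)
        return FeatureBlock(
            "B", "binary", m, [f"f{j}" for j in range(m.shape[1])],
            [f"r{i}" for i in range(m.shape[0])],
        )

    def test_identical_disjoint_and_half(self):
        s, _ = tanimoto_matrix(self._bin([[1, 1, 0, 0], [1, 1, 0, 0]]))
        assert s[0, 1] == 1.0
        s, _ = tanimoto_matrix(self._bin([[1, 1, 0, 0], [0, 0, 1, 1]]))
        assert s[0, 1] == 0.0
        s, _ = tanimoto_matrix(self._bin([[1, 1, 0, 1], [1, 0, 1, 1]]))
        assert s[0, 1] == pytest.approx(0.5)  # intersection 2, union 4

    def test_symmetric_unit_diagonal_bounded(self, smiles_ds):
        fp = compute_fingerprint(smiles_ds, "MACCS")
        s, mean_off = tanimoto_matrix(fp)
        np.testing.assert_allclose(s, s.T)
        assert ((0 <= s) & (s <= 1)).all()
        assert np.allclose(np.diag(s)[fp.matrix.sum(axis=1) > 0], 1.0)
        assert 0 <= mean_off <= 1

    def test_both_empty_pair_is_one(self):
        s, _ = tanimoto_matrix(self._bin([[0, 0], [0, 0]]))
        assert s[0, 1] == 1.0

    def test_continuous_block_rejected(self, smiles_ds):
        blk = compute_descriptors(smiles_ds, "13MD")
        with pytest.raises(FeaturizationError, match="binary"):
            tanimoto_matrix(blk)


class TestBasicProperties:
    def test_structure_forced_values(self):
        ds = _ds(("c1ccccc1", 0), ("CCCC", 0), ("O", 0))
        props = basic_properties(ds)
        assert props[0].nRing == 1
        assert props[1].nRot == 1  # n-butane: one non-terminal single bond
        assert props[2].MW == pytest.approx(18.02, abs=0.01)
        assert props[2].nRot == 0 and props[2].nRing == 0


def test_smarts_catalog_block(smiles_ds):
    blk = smarts_catalog_block(smiles_ds, ["c1ccccc1", "[OX2H]"], name="CAT")
    assert blk.matrix.shape == (len(smiles_ds), 2)
    # benzene row (FIX04) matches the aromatic pattern, not hydroxyl
    i = smiles_ds.ids.index("FIX04")
    assert blk.matrix[i].tolist() == [1.0, 0.0]
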