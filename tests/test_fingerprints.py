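"""Fingerprint encoding, Tanimoto similarity, and substructure checks."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import MACCSkeys

from fpgan.fingerprints import (
    BitFingerprint,
    FingerprintError,
    MoleculeRecord,
    bit_containment,
    confirm_substructure,
    encode_fp2,
    encode_maccs,
    fingerprints_to_matrix,
    read_fingerprints,
    read_molecules,
    tanimoto,
    tanimoto_matrix,
    write_fingerprints,
)


class TestEncodeMaccs:
    def test_methane_low_popcount(self):
        fp = encode_maccs("C")
        assert fp.length == 168
        assert 0 < fp.popcount() <= 5

    def test_canonicalization_invariance(self):
        assert encode_maccs("CCO") == encode_maccs("OCC")

    def test_matches_reference_toolkit_padded(self, druglike_smiles):
        """Bits agree with the toolkit's native MACCS keys, zero-padded."""
        for _name, smi in druglike_smiles:
            fp = encode_maccs(smi)
            native = MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(smi))
            expected = np.zeros(168, dtype=np.uint8)
            for idx in native.GetOnBits():
                expected[idx] = 1
            assert np.array_equal(fp.bits, expected)

    def test_padding_positions_constant_zero(self, druglike_smiles):
        for _name, smi in druglike_smiles:
            assert encode_maccs(smi).bits[167] == 0

    def test_unparsable_smiles_raises_with_offender(self):
        with pytest.raises(FingerprintError, match="not_a_smiles"):
            encode_maccs(MoleculeRecord("bad", "not_a_smiles"))

    def test_length_below_native_keys_rejected(self):
        with pytest.raises(FingerprintError):
            encode_maccs("CCO", length=100)


class TestEncodeFp2:
    def test_near_empty_for_methane(self):
        fp = encode_fp2("C")
        assert fp.length == 1024
        assert fp.popcount() <= 4

    def test_deterministic(self):
        assert encode_fp2("CC(=O)Oc1ccccc1C(=O)O") == encode_fp2("CC(=O)Oc1ccccc1C(=O)O")

    def test_matches_reference_path_fingerprint(self, druglike_smiles):
        for _name, smi in druglike_smiles:
            fp = encode_fp2(smi)
            ref = Chem.RDKFingerprint(Chem.MolFromSmiles(smi), minPath=1,
                                      maxPath=7, fpSize=1024)
            assert set(np.flatnonzero(fp.bits)) == set(ref.GetOnBits())


class TestTanimoto:
    def test_identity_is_one(self):
        fp = encode_maccs("CC(=O)Oc1ccccc1C(=O)O")
        assert tanimoto(fp, fp) == 1.0

    def test_hand_computed_third(self):
        a = np.zeros(168, dtype=np.uint8)
        b = np.zeros(168, dtype=np.uint8)
        a[[0, 1]] = 1
        b[[0, 2]] = 1
        assert tanimoto(BitFingerprint(a, "MACCS"),
                        BitFingerprint(b, "MACCS")) == pytest.approx(1 / 3)

    def test_all_zero_pair_scores_zero(self):
        z = BitFingerprint(np.zeros(168, dtype=np.uint8), "MACCS")
        assert tanimoto(z, z) == 0.0

    def test_scheme_mismatch_rejected(self):
        a = encode_maccs("CCO")
        b = encode_fp2("CCO")
        with pytest.raises(FingerprintError):
            tanimoto(a, b)

    def test_matches_bruteforce_on_random_pairs(self, rng):
        """Vectorized Tanimoto equals the naive per-bit loop, 1,000 pairs."""
        a = (rng.random((1000, 64)) < 0.4).astype(np.uint8)
        b = (rng.random((1000, 64)) < 0.4).astype(np.uint8)
        fast = np.array([
            tanimoto(BitFingerprint(x, "RAW64"), BitFingerprint(y, "RAW64"))
            for x, y in zip(a, b)
        ])
        slow = []
        for x, y in zip(a, b):
            inter = sum(1 for i in range(64) if x[i] and y[i])
            union = sum(1 for i in range(64) if x[i] or y[i])
            slow.append(inter / union if union else 0.0)
        assert np.allclose(fast, slow)

    def test_matrix_agrees_with_scalar(self, rng):
        a = (rng.random((30, 168)) < 0.3).astype(np.uint8)
        b = (rng.random((20, 168)) < 0.3).astype(np.uint8)
        mat = tanimoto_matrix(a, b)
        for i in (0, 7, 29):
            for j in (0, 11, 19):
                assert mat[i, j] == pytest.approx(tanimoto(
                    BitFingerprint(a[i], "MACCS"), BitFingerprint(b[j], "MACCS")))

    def test_symmetry_and_range(self, rng):
        a = (rng.random((50, 168)) < 0.3).astype(np.uint8)
        mat = tanimoto_matrix(a, a)
        assert np.allclose(mat, mat.T)
        assert mat.min() >= 0.0 and mat.max() <= 1.0
        nonzero = a.sum(axis=1) > 0
        assert np.allclose(np.diag(mat)[nonzero], 1.0)


class TestContainmentAndConfirmation:
    def test_zero_query_contained_everywhere(self):
        z = BitFingerprint(np.zeros(168, dtype=np.uint8), "MACCS")
        fp = encode_maccs("CCO")
        assert bit_containment(z, fp)

    def test_self_containment(self):
        fp = encode_maccs("CCO")
        assert bit_containment(fp, fp)

    def test_benzene_in_toluene_not_cyclohexane(self):
        assert confirm_substructure("c1ccccc1", "Cc1ccccc1")
        assert not confirm_substructure("c1ccccc1", "C1CCCCC1")

    def test_invalid_pattern_rejected(self):
        with pytest.raises(FingerprintError):
            confirm_substructure("][", "CCO")

    def test_screen_has_no_false_negatives_on_planted_cores(self, planted_library):
        """Subgraph-confirmed molecules always pass the MACCS bit screen."""
        from fpgan.dataset import DEFAULT_CORE_SMILES

        records, truth = planted_library
        core_fp = encode_maccs(DEFAULT_CORE_SMILES)
        for rec, has_core in zip(records[:300], truth[:300]):
            if has_core:
                assert bit_containment(core_fp, encode_maccs(rec))

    def test_fp2_screen_no_false_negatives(self, planted_library):
        from fpgan.dataset import DEFAULT_CORE_SMILES

        records, truth = planted_library
        core_fp = encode_fp2(DEFAULT_CORE_SMILES)
        for rec, has_core in zip(records[:150], truth[:150]):
            if has_core:
                assert bit_containment(core_fp, encode_fp2(rec))


class TestBitFingerprintType:
    def test_rejects_non_binary(self):
        with pytest.raises(FingerprintError):
            BitFingerprint(np.array([0, 1, 2] + [0] * 165), "MACCS")

    def test_rejects_wrong_scheme_length(self):
        with pytest.raises(FingerprintError):
            BitFingerprint(np.zeros(100, dtype=np.uint8), "MACCS")

    def test_bitstring_roundtrip(self):
        fp = encode_maccs("CC(=O)Oc1ccccc1C(=O)O")
        back = BitFingerprint.from_bitstring(fp.to_bitstring(), "MACCS")
        assert back == fp


class TestIO:
    def test_fingerprint_csv_roundtrip(self, tmp_path, druglike_smiles):
        fps = [encode_maccs(MoleculeRecord(name, smi))
               for name, smi in druglike_smiles[:5]]
        path = tmp_path / "fps.csv"
        write_fingerprints(fps, path)
        back = read_fingerprints(path)
        assert back == fps
        assert [f.molecule_id for f in back] == [n for n, _ in druglike_smiles[:5]]

    def test_read_smi_and_csv(self, tmp_path):
        (tmp_path / "lib.smi").write_text("CCO\tethanol\nc1ccccc1\tbenzene\n")
        recs = read_molecules(tmp_path / "lib.smi")
        assert [r.molecule_id for r in recs] == ["ethanol", "benzene"]
        (tmp_path / "lib.csv").write_text("smiles,id\nCCO,ethanol\n")
        recs = read_molecules(tmp_path / "lib.csv")
        assert recs[0].smiles == "CCO"

    def test_matrix_roundtrip_requires_consistency(self):
        a = encode_maccs("CCO")
        b = encode_fp2("CCO")
        with pytest.raises(FingerprintError):
            fingerprints_to_matrix([a, b])
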