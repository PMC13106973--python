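import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmhcnet import dataprep as dp
from pmhcnet import geometry as geo
from pmhcnet import residues as rc


class TestAffinityTransform:
    def test_reference_points(self):
        assert dp.ba_target(1.0) == pytest.approx(1.0)
        assert dp.ba_target(50000.0) == pytest.approx(0.0)
        assert dp.ba_target(500.0) == pytest.approx(
            1.0 - np.log(500.0) / np.log(50000.0))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e8),
           st.floats(min_value=1e-3, max_value=1e8))
    def test_strictly_decreasing(self, a, b):
        if a == b:
            return
        lo, hi = min(a, b), max(a, b)
        assert dp.ba_target(lo) > dp.ba_target(hi)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            dp.ba_target(0.0)
        with pytest.raises(ValueError):
            dp.classify_binder(-5.0)

    def test_binder_boundary(self):
        assert dp.classify_binder(499.0)
        assert not dp.classify_binder(500.0)
        assert not dp.classify_binder(501.0)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e7))
    def test_classification_consistent_with_target(self, kd):
        assert dp.classify_binder(kd) == (
            dp.ba_target(kd) > dp.ba_target(500.0))


class TestOneHot:
    def test_single_alanine(self):
        row = dp.one_hot("A")[0]
        assert row[rc.AA1_TO_INDEX["A"]] == 1.0 and row.sum() == 1.0

    def test_rows_sum_to_one_and_reserved_channels(self):
        m = dp.one_hot("ARNDCQEGHILKMFPSTWYV")
        assert m.shape == (20, 32)
        assert np.all(m.sum(axis=1) == 1.0)
        assert np.all(m[:, 20:] == 0.0)

    def test_nonstandard_letter_rejected(self):
        with pytest.raises(ValueError):
            dp.one_hot("AXA")


class TestProximity:
    def test_diagonal_and_symmetry(self, toy_complex):
        cx, _, _ = toy_complex
        P = dp.proximity_matrix(cx)
        assert np.allclose(np.diag(P), 1.0)
        assert np.allclose(P, P.T)
        assert np.all((P > 0) & (P <= 1))

    def test_two_single_atom_residues(self):
        coords = np.zeros((2, rc.N_ATOM_SLOTS, 3))
        coords[1, 0, 0] = 1.0
        mask = np.zeros((2, rc.N_ATOM_SLOTS), dtype=bool)
        mask[:, 0] = True
        P = dp.proximity_matrix(coords, mask)
        assert P[0, 1] == pytest.approx(0.5)  # 1 / (1 + 1 A)

    def test_matches_brute_force(self, toy_complex):
        cx, _, _ = toy_complex
        P = dp.proximity_matrix(cx)
        r = len(cx.mhc_seq)
        rng = np.random.default_rng(0)
        for i, j in rng.integers(0, r, size=(20, 2)):
            best = np.inf
            for a in np.flatnonzero(cx.mhc_mask[i]):
                for b in np.flatnonzero(cx.mhc_mask[j]):
                    best = min(best, np.linalg.norm(
                        cx.mhc_coords[i, a] - cx.mhc_coords[j, b]))
            if i == j:
                best = 0.0
            assert P[i, j] == pytest.approx(1.0 / (1.0 + best))

    def test_permutation_consistency(self, toy_complex):
        cx, _, _ = toy_complex
        P = dp.proximity_matrix(cx)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(cx.mhc_seq))
        P2 = dp.proximity_matrix(cx.mhc_coords[perm], cx.mhc_mask[perm])
        assert np.allclose(P2, P[np.ix_(perm, perm)])


class TestPDBRoundTrip:
    def test_round_trip(self, toy_complex, tmp_path):
        cx, _, _ = toy_complex
        path = tmp_path / "cx.pdb"
        dp.write_pdb(cx, path)
        back = dp.read_pdb(path)
        assert back.pep_seq == cx.pep_seq and back.mhc_seq == cx.mhc_seq
        assert np.abs(back.pep_coords - cx.pep_coords)[cx.pep_mask].max() <= 1e-3
        assert np.abs(back.mhc_coords - cx.mhc_coords)[cx.mhc_mask].max() <= 1e-3
        assert np.array_equal(back.pep_resnums, cx.pep_resnums)

    def test_missing_peptide_chain(self, toy_complex, tmp_path):
        cx, _, _ = toy_complex
        path = tmp_path / "cx.pdb"
        dp.write_pdb(cx, path)
        with pytest.raises(ValueError, match="peptide chain"):
            dp.read_pdb(path, peptide_chain="Z")

    def test_altloc_keeps_highest_occupancy(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  N   ALA P   1       0.000   1.400   0.000  1.00  0.00           N",
            "ATOM      2  CA AALA P   1       0.000   0.000   0.000  0.40  0.00           C",
            "ATOM      3  CA BALA P   1       9.000   0.000   0.000  0.60  0.00           C",
            "ATOM      4  C   ALA P   1       1.500   0.000   0.000  1.00  0.00           C",
            "ATOM      5  O   ALA P   1       2.100   1.000   0.000  1.00  0.00           O",
            "ATOM      6  CB  ALA P   1      -0.500  -0.800   1.200  1.00  0.00           C",
            "ATOM      7  N   GLY M   1      20.000   1.400   0.000  1.00  0.00           N",
            "ATOM      8  CA  GLY M   1      20.000   0.000   0.000  1.00  0.00           C",
            "ATOM      9  C   GLY M   1      21.500   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        path = tmp_path / "altloc.pdb"
        path.write_text(pdb + "\n")
        cx = dp.read_pdb(path)
        assert cx.pep_coords[0, 1, 0] == pytest.approx(9.0)  # occupancy 0.60

    def test_missing_backbone_reported(self, tmp_path):
        pdb = "\n".join([
            "ATOM      1  N   ALA P   1       0.000   1.400   0.000  1.00  0.00           N",
            "ATOM      2  CA  ALA P   1       0.000   0.000   0.000  1.00  0.00           C",
            "ATOM      7  N   GLY M   1      20.000   1.400   0.000  1.00  0.00           N",
            "ATOM      8  CA  GLY M   1      20.000   0.000   0.000  1.00  0.00           C",
            "ATOM      9  C   GLY M   1      21.500   0.000   0.000  1.00  0.00           C",
            "END",
        ])
        path = tmp_path / "broken.pdb"
        path.write_text(pdb + "\n")
        with pytest.raises(ValueError, match="ALA1"):
            dp.read_pdb(path)


class TestSuperposition:
    def test_self_is_identity(self, toy_complex):
        cx, _, _ = toy_complex
        out, R, t = dp.superpose_to_reference(cx, cx, return_transform=True)
        assert np.allclose(R, np.eye(3), atol=1e-8)
        assert np.allclose(t, 0.0, atol=1e-7)

    def test_recovers_rigid_motion(self, toy_complex):
        cx, _, _ = toy_complex
        rng = np.random.default_rng(2)
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        R = geo.quat_to_matrix(q)
        moved = cx.transformed(R, np.array([4.0, -2.0, 9.0]))
        back = dp.superpose_to_reference(moved, cx)
        assert np.abs(back.mhc_coords - cx.mhc_coords)[cx.mhc_mask].max() <= 1e-6
        assert np.abs(back.pep_coords - cx.pep_coords)[cx.pep_mask].max() <= 1e-6

    def test_outliers_rejected(self, toy_complex):
        cx, _, _ = toy_complex
        noisy = dp.PMHCComplex(
            cx.entry_id, cx.allele, cx.mhc_seq, cx.mhc_coords.copy(),
            cx.mhc_mask, cx.pep_seq, cx.pep_coords, cx.pep_mask,
        )
        bad = [3, 11, 20, 30, 44]
        noisy.mhc_coords[bad] += np.array([6.0, 0.0, 0.0])
        out, R, t = dp.superpose_to_reference(noisy, cx, return_transform=True)
        # fit equals the clean-subset Kabsch: identity here
        assert np.allclose(R, np.eye(3), atol=1e-8)
        assert np.allclose(t, 0.0, atol=1e-6)

    def test_idempotent(self, toy_complex):
        cx, _, _ = toy_complex
        moved = cx.transformed(geo.quat_to_matrix(
            geo.matrix_to_quat(np.eye(3))), np.array([1.0, 2.0, 3.0]))
        once = dp.superpose_to_reference(moved, cx)
        twice = dp.superpose_to_reference(once, cx)
        assert np.abs(twice.mhc_coords - once.mhc_coords).max() <= 1e-6

    def test_low_identity_rejected(self, toy_complex):
        cx, _, _ = toy_complex
        mutated = "".join(
            a if i % 3 == 0 else ("W" if a != "W" else "F")
            for i, a in enumerate(cx.mhc_seq)
        )
        other = dp.PMHCComplex(
            "x", "", mutated, cx.mhc_coords, cx.mhc_mask,
            cx.pep_seq, cx.pep_coords, cx.pep_mask,
        )
        with pytest.raises(ValueError, match="identity"):
            dp.superpose_to_reference(other, cx)


class TestCrossMask:
    def test_infinite_cutoff_unmasks_all(self, toy_complex):
        cx, _, _ = toy_complex
        assert dp.build_cross_mask(cx, cutoff=np.inf).all()

    def test_zero_cutoff_masks_all(self, toy_complex):
        cx, _, _ = toy_complex
        assert not dp.build_cross_mask(cx, cutoff=0.0).any()

    def test_far_residue_masked(self, toy_complex):
        cx, _, _ = toy_complex
        moved = dp.PMHCComplex(
            cx.entry_id, cx.allele, cx.mhc_seq, cx.mhc_coords.copy(),
            cx.mhc_mask, cx.pep_seq, cx.pep_coords, cx.pep_mask,
        )
        near = dp.build_cross_mask(cx, cutoff=15.0)
        idx = int(np.flatnonzero(near)[0])
        moved.mhc_coords[idx] += 50.0
        m = dp.build_cross_mask(moved, cutoff=15.0)
        assert not m[idx]
        assert np.array_equal(m[near], np.r_[False, near[near][1:]]) or \
            (m ^ near).sum() == 1


class TestDatasetStore:
    def test_round_trip_bit_identical(self, toy_bundles, tmp_path):
        path = tmp_path / "ds.h5"
        assert dp.build_dataset(toy_bundles, path) == len(toy_bundles)
        with dp.load_dataset(path) as ds:
            for b in toy_bundles:
                back = ds[b.entry_id]
                assert np.array_equal(back.proximity, b.proximity)
                assert np.array_equal(back.gt_atoms, b.gt_atoms)
                assert back.affinity == b.affinity
                assert back.binder == b.binder

    def test_unlabeled_record(self, toy_complex, tmp_path):
        cx, _, _ = toy_complex
        b = dp.bundle_from_complex(cx)  # no Kd
        path = tmp_path / "ds.h5"
        dp.build_dataset([b], path)
        with dp.load_dataset(path) as ds:
            back = ds[0]
            assert back.affinity is None and not back.has_label

    def test_duplicate_ids_rejected(self, toy_bundles, tmp_path):
        with pytest.raises(ValueError, match="duplicate"):
            dp.build_dataset([toy_bundles[0], toy_bundles[0]],
                             tmp_path / "dup.h5")

    def test_corrupted_file_errors(self, tmp_path):
        path = tmp_path / "bad.h5"
        path.write_bytes(b"this is not hdf5 at all")
        with pytest.raises(OSError):
            dp.load_dataset(path)
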