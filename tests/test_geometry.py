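import numpy as np
import pytest

from pmhcnet import geometry as geo
from pmhcnet import residues as rc
from pmhcnet.geometry import Frame


def random_frame(rng):
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    return Frame(q, rng.uniform(-10, 10, 3))


class TestQuaternions:
    def test_identity(self):
        assert np.allclose(geo.quat_to_matrix([1, 0, 0, 0]), np.eye(3))

    def test_half_turn_about_x(self):
        assert np.allclose(geo.quat_to_matrix([0, 1, 0, 0]),
                           np.diag([1.0, -1.0, -1.0]))

    def test_matches_rodrigues_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            theta = rng.uniform(-np.pi, np.pi)
            q = np.concatenate([[np.cos(theta / 2)],
                                np.sin(theta / 2) * axis])
            K = np.array([[0, -axis[2], axis[1]],
                          [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            R_oracle = np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * K @ K
            assert np.abs(geo.quat_to_matrix(q) - R_oracle).max() <= 1e-10

    def test_orthonormal_det_plus_one_and_roundtrip(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            q = rng.standard_normal(4)
            q /= np.linalg.norm(q)
            R = geo.quat_to_matrix(q)
            assert np.allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(R), 1.0)
            q2 = geo.matrix_to_quat(R)
            assert np.allclose(q2, q, atol=1e-9) or np.allclose(q2, -q, atol=1e-9)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError):
            geo.quat_to_matrix([1.0, 0.1, 0, 0])


class TestFrameAlgebra:
    def test_identity_compose(self):
        rng = np.random.default_rng(2)
        f = random_frame(rng)
        out = geo.compose_frames(Frame.identity(), f)
        assert np.allclose(out.to_matrix4(), f.to_matrix4(), atol=1e-12)

    def test_inverse_gives_identity(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            f = random_frame(rng)
            ident = geo.compose_frames(f, f.inverse()).to_matrix4()
            assert np.abs(ident - np.eye(4)).max() <= 1e-9

    def test_matches_homogeneous_matrix_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            a, b = random_frame(rng), random_frame(rng)
            got = geo.compose_frames(a, b).to_matrix4()
            want = a.to_matrix4() @ b.to_matrix4()
            assert np.abs(got - want).max() <= 1e-9

    def test_associativity(self):
        rng = np.random.default_rng(5)
        a, b, c = (random_frame(rng) for _ in range(3))
        left = geo.compose_frames(geo.compose_frames(a, b), c).to_matrix4()
        right = geo.compose_frames(a, geo.compose_frames(b, c)).to_matrix4()
        assert np.abs(left - right).max() <= 1e-9

    def test_unit_norm_invariant(self):
        rng = np.random.default_rng(6)
        f = random_frame(rng)
        for _ in range(1000):
            f = geo.compose_frames(f, random_frame(rng))
        assert abs(np.linalg.norm(f.quaternion) - 1.0) <= 1e-6


class TestFrameFromBackbone:
    def test_canonical_pose_gives_identity(self):
        # CA at origin, C on +x, N in the xy-plane -> identity rotation
        f = geo.frame_from_backbone([0.5, 1.4, 0.0], [0, 0, 0], [1.5, 0, 0])
        assert np.allclose(f.rotation_matrix, np.eye(3), atol=1e-12)
        assert np.allclose(f.translation, 0.0)

    def test_equivariance_under_rigid_motion(self):
        rng = np.random.default_rng(7)
        n, ca, c = rng.standard_normal((3, 3)) * 2 + [[0, 1, 0], [0, 0, 0], [1, 0, 0]]
        f = geo.frame_from_backbone(n, ca, c)
        for _ in range(20):
            g = random_frame(rng)
            moved = geo.frame_from_backbone(g.apply(n), g.apply(ca), g.apply(c))
            want = geo.compose_frames(g, f).to_matrix4()
            assert np.abs(moved.to_matrix4() - want).max() <= 1e-9

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            geo.frame_from_backbone([2, 0, 0], [0, 0, 0], [1, 0, 0])


class TestRigidGroups:
    def test_every_heavy_atom_in_exactly_one_group(self):
        for aa3 in rc.AA3_ORDER:
            members = rc.group_members(aa3)
            heavy = [a for g, atoms in members.items() for a in atoms
                     if a != "H"]
            assert sorted(heavy) == sorted(rc.get_layout(aa3).atom14_names)

    def test_backbone_torsion_group_sizes(self):
        for aa3 in rc.AA3_ORDER:
            members = rc.group_members(aa3)
            assert members["omega"] == []
            assert members["psi"] == ["O"]
            if aa3 != "PRO":
                assert members["phi"] == ["H"]

    def test_atom_slots_stable_and_bounded(self):
        for aa3 in rc.AA3_ORDER:
            lay = rc.get_layout(aa3)
            assert lay.atom14_names[:4] == ("N", "CA", "C", "O")
            assert len(lay.atom14_names) <= rc.N_ATOM_SLOTS
        assert len(rc.get_layout("TRP").atom14_names) == rc.N_ATOM_SLOTS


class TestPlacementAndTorsions:
    def test_glycine_emits_backbone_only(self):
        angles = np.zeros((1, 7))
        defined = np.zeros((1, 7), dtype=bool)
        angles[0, 1] = -40.0
        defined[0, 1] = True
        coords, mask = geo.place_atoms([Frame.identity()],
                                       geo.TorsionSet(angles, defined), "G")
        assert mask[0].sum() == 4  # N, CA, C, O

    def test_omega_moves_no_own_atoms(self, random_nine_mer):
        seq, frames, tors, coords, mask = random_nine_mer
        angles = tors.angles_deg.copy()
        angles[4, 2] = 37.0  # drastically different omega for residue 4
        coords2, _ = geo.place_atoms(frames, geo.TorsionSet(angles, tors.defined),
                                     seq)
        assert np.abs(coords2 - coords).max() == 0.0

    def test_round_trip_reproduces_atoms(self, random_nine_mer):
        seq, frames, tors, coords, mask = random_nine_mer
        tors2 = geo.extract_torsions(coords, seq, mask)
        frames2 = geo.frames_from_atoms(coords)
        coords2, _ = geo.place_atoms(frames2, tors2, seq)
        assert np.abs(coords2 - coords)[mask].max() <= 1e-3

    def test_round_trip_angles(self, random_nine_mer):
        seq, frames, tors, coords, mask = random_nine_mer
        tors2 = geo.extract_torsions(coords, seq, mask)
        assert np.array_equal(tors.defined, tors2.defined)
        diff = np.abs(((tors2.angles_deg - tors.angles_deg + 180) % 360) - 180)
        assert diff[tors.defined].max() <= 1e-4

    def test_trans_peptide_bond_omega(self, random_nine_mer):
        seq, frames, tors, coords, mask = random_nine_mer
        got = geo.extract_torsions(coords, seq, mask)
        assert np.allclose(got.angles_deg[1:, 2], 180.0, atol=1e-6) or \
            np.abs(np.abs(got.angles_deg[1:, 2]) - 180.0).max() <= 1e-6

    def test_constructed_dihedral(self):
        # four points engineered to a 60-degree dihedral
        p1 = np.array([0.0, 1.0, 0.0])
        p2 = np.zeros(3)
        p3 = np.array([1.5, 0.0, 0.0])
        p4 = p3 + np.array([0.0, np.cos(np.radians(60)), np.sin(np.radians(60))])
        assert abs(float(rc.dihedral(p1, p2, p3, p4)) - 60.0) <= 1e-6

    def test_first_residue_phi_undefined(self, random_nine_mer):
        seq, frames, tors, coords, mask = random_nine_mer
        got = geo.extract_torsions(coords, seq, mask)
        assert not got.defined[0, 0] and not got.defined[0, 2]

    def test_missing_atom_flags_undefined(self, random_nine_mer):
        seq, frames, tors, coords, mask = random_nine_mer
        m = mask.copy()
        lay = rc.get_layout(rc.AA1_TO_AA3[seq[2]])
        m[2, lay.slot("CB")] = False  # CB defines chi1-chi3 of lysine
        got = geo.extract_torsions(coords, seq, m)
        assert not got.defined[2, 3:6].any()
        assert got.defined[2, 6]  # chi4 (CG-CD-CE-NZ) does not use CB

    def test_undefined_required_torsion_raises(self):
        angles = np.zeros((1, 7))
        defined = np.zeros((1, 7), dtype=bool)
        defined[0, 1] = True  # psi present, chi1 missing
        with pytest.raises(ValueError, match="chi1"):
            geo.place_atoms([Frame.identity()],
                            geo.TorsionSet(angles, defined), "S")

    def test_placement_is_all_L(self, random_nine_mer):
        from pmhcnet import structqc as qc
        seq, frames, tors, coords, mask = random_nine_mer
        calls = qc.chirality_calls(coords, mask, seq)
        assert all(c in ("L", "achiral") for c in calls)


class TestChiralHydrogen:
    def test_glycine_noop(self):
        lay = rc.get_layout("GLY")
        assert geo.place_chiral_hydrogen(lay.ideal_atom14, "G") is None

    def test_l_alanine_sign(self):
        lay = rc.get_layout("ALA")
        co = lay.ideal_atom14
        ha = geo.place_chiral_hydrogen(co, "A")
        # signed volume of (N, C, CB) around CA with HA on the opposite side
        sv = np.linalg.det(np.stack([co[0] - co[1], co[2] - co[1],
                                     co[4] - co[1]]))
        sv_ha = np.linalg.det(np.stack([co[0] - co[1], co[2] - co[1],
                                        ha - co[1]]))
        assert sv > 0 and sv_ha < 0  # L residue, H on the opposite face

    def test_mirror_symmetry(self):
        lay = rc.get_layout("ALA")
        co = lay.ideal_atom14.copy()
        ha = geo.place_chiral_hydrogen(co, "A")
        mirrored = co * np.array([1.0, 1.0, -1.0])
        ha_m = geo.place_chiral_hydrogen(mirrored, "A")
        assert np.allclose(ha_m, ha * np.array([1.0, 1.0, -1.0]), atol=1e-12)
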