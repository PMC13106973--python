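import numpy as np
import pytest

import pmhcnet.autograd as ag
from pmhcnet import dataprep as dp
from pmhcnet import fixtures as fx
from pmhcnet import geometry as geo
from pmhcnet import network as nn
from pmhcnet import residues as rc


@pytest.fixture(scope="module")
def bundle():
    return fx.make_toy_dataset(1, fx.FixtureSpec(seed=5))[0]


@pytest.fixture(scope="module")
def model():
    return nn.Model(nn.ModelConfig(seed=1, mhc_blocks=1, cross_blocks=2,
                                   pep_blocks=2, dtype="float64"))


from oracles import naive_ipa, naive_peptide_blocks  # noqa: E402


class TestMHCSelfIPA:
    def test_zeroed_output_projection_is_identity(self, model, bundle):
        import copy
        m = nn.Model(model.config)
        for k, p in m.params.items():
            if k.endswith("out.W") or "mlp.fc2" in k:
                p.data = np.zeros_like(p.data)
        x = np.random.default_rng(0).standard_normal((len(bundle.mhc_seq), 32))
        y = m.mhc_self_ipa(ag.Tensor(x), bundle.mhc_rot, bundle.mhc_trans,
                           bundle.proximity, bundle.cross_mask)
        assert np.abs(y.data - x).max() == 0.0

    def test_invariant_under_global_rigid_motion(self, model, bundle):
        x = ag.Tensor(np.random.default_rng(1).standard_normal(
            (len(bundle.mhc_seq), 32)))
        base = model.mhc_self_ipa(x, bundle.mhc_rot, bundle.mhc_trans,
                                  bundle.proximity, bundle.cross_mask)
        q = np.array([0.2, -0.5, 0.7, 0.45])
        q /= np.linalg.norm(q)
        R = geo.quat_to_matrix(q)
        t = np.array([11.0, -3.0, 8.0])
        moved = model.mhc_self_ipa(
            x, np.einsum("ab,rbc->rac", R, bundle.mhc_rot),
            bundle.mhc_trans @ R.T + t, bundle.proximity, bundle.cross_mask)
        assert np.abs(base.data - moved.data).max() <= 1e-5

    def test_matches_loop_oracle(self, model):
        rng = np.random.default_rng(2)
        rj = 3
        feats = rng.standard_normal((rj, 32))
        rot = np.stack([geo.quat_to_matrix(q / np.linalg.norm(q))
                        for q in rng.standard_normal((rj, 4))])
        trans = rng.uniform(-5, 5, (rj, 3))
        prox = rng.uniform(0, 1, (rj, rj))
        prox = (prox + prox.T) / 2
        np.fill_diagonal(prox, 1.0)
        got = model._ipa("mhc0.", ag.Tensor(feats), ag.Tensor(feats),
                         rot, trans, rot, trans, proximity=prox)
        want = naive_ipa(model, "mhc0.", feats, feats, rot, trans, rot, trans,
                         proximity=prox)
        assert np.abs(got.data - want).max() <= 1e-5


class TestPeptideSelfAttention:
    def test_single_residue_depends_only_on_itself(self, model):
        x1 = np.random.default_rng(3).standard_normal((1, 32))
        y1 = model.peptide_self_attention(ag.Tensor(x1))
        assert y1.shape == (1, 32)

    def test_empty_rejected(self, model):
        with pytest.raises(ValueError):
            model.peptide_self_attention(ag.Tensor(np.zeros((0, 32))))

    def test_relative_encoding_shift_invariance(self, model):
        # absolute indices never enter: the module sees only features and
        # relative offsets, so the same features give the same output no
        # matter where the window nominally sits
        x = np.random.default_rng(4).standard_normal((6, 32))
        a = model.peptide_self_attention(ag.Tensor(x))
        b = model.peptide_self_attention(ag.Tensor(x.copy()))
        assert np.array_equal(a.data, b.data)

    def test_matches_loop_oracle(self, model):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((4, 32))
        got = model.peptide_self_attention(ag.Tensor(x))
        want = naive_peptide_blocks(model, x)
        assert np.abs(got.data - want).max() <= 1e-5


class TestCrossAttentionStructure:
    def test_zero_blocks_keeps_identity_frames(self, bundle):
        m = nn.Model(nn.ModelConfig(seed=1, cross_blocks=0, dtype="float64"))
        x = ag.Tensor(np.random.default_rng(6).standard_normal((9, 32)))
        feats = ag.Tensor(np.random.default_rng(7).standard_normal(
            (len(bundle.mhc_seq), 32)))
        _, rot, trans, _ = m.cross_attention_structure(
            x, feats, bundle.mhc_rot, bundle.mhc_trans, bundle.cross_mask)
        assert np.array_equal(rot.data, np.broadcast_to(np.eye(3), (9, 3, 3)))
        assert np.array_equal(trans.data, np.zeros((9, 3)))

    def test_rotations_stay_unit(self, model, bundle):
        x = ag.Tensor(np.random.default_rng(8).standard_normal((9, 32)))
        feats = ag.Tensor(np.random.default_rng(9).standard_normal(
            (len(bundle.mhc_seq), 32)))
        # randomize the frame heads so updates are non-trivial
        for k, p in model.params.items():
            if "frame_update" in k and k.endswith("W"):
                p.data = 0.3 * np.random.default_rng(10).standard_normal(
                    p.data.shape)
        _, rot, trans, _ = model.cross_attention_structure(
            x, feats, bundle.mhc_rot, bundle.mhc_trans, bundle.cross_mask)
        RtR = rot.data @ np.swapaxes(rot.data, 1, 2)
        assert np.abs(RtR - np.eye(3)).max() <= 1e-6
        for k, p in model.params.items():
            if "frame_update" in k and k.endswith("W"):
                p.data = np.zeros_like(p.data)

    def test_update_composition_matches_matrix_oracle(self):
        rng = np.random.default_rng(11)
        rot = np.broadcast_to(np.eye(3), (1, 3, 3)).copy()
        trans = np.zeros((1, 3))
        M = np.eye(4)
        for _ in range(5):
            head = rng.standard_normal(6) * 0.4
            quat = np.concatenate([[1.0], head[:3]])
            quat /= np.linalg.norm(quat)
            Ru = geo.quat_to_matrix(quat)
            tu = head[3:] * 10.0
            step = np.eye(4)
            step[:3, :3] = Ru
            step[:3, 3] = tu
            M = M @ step
            # package-style update
            trans = (rot[0] @ tu) + trans
            rot = (rot[0] @ Ru)[None]
        assert np.abs(rot[0] - M[:3, :3]).max() <= 1e-9
        assert np.abs(trans[0] - M[:3, 3]).max() <= 1e-9

    def test_all_masked_rejected(self, model, bundle):
        x = ag.Tensor(np.zeros((9, 32)))
        feats = ag.Tensor(np.zeros((len(bundle.mhc_seq), 32)))
        with pytest.raises(ValueError):
            model.cross_attention_structure(
                x, feats, bundle.mhc_rot, bundle.mhc_trans,
                np.zeros(len(bundle.mhc_seq), dtype=bool))

    def test_masked_residue_has_zero_influence(self, model, bundle):
        x = ag.Tensor(np.random.default_rng(12).standard_normal((9, 32)))
        feats = np.random.default_rng(13).standard_normal(
            (len(bundle.mhc_seq), 32))
        mask = bundle.cross_mask.copy()
        victim = int(np.flatnonzero(mask)[2])
        mask[victim] = False
        base = model.cross_attention_structure(
            x, ag.Tensor(feats), bundle.mhc_rot, bundle.mhc_trans, mask)
        perturbed = feats.copy()
        perturbed[victim] += 1e6
        out = model.cross_attention_structure(
            x, ag.Tensor(perturbed), bundle.mhc_rot, bundle.mhc_trans, mask)
        for a, b in zip(base[:4], out[:4]):
            assert np.array_equal(a.data, b.data)


class TestBAHead:
    def test_single_residue(self, model):
        x = np.random.default_rng(14).standard_normal((1, 32))
        got = float(model.ba_head(ag.Tensor(x)).data)
        want = float(model.ba_head(ag.Tensor(np.vstack([x]))).data)
        assert got == want

    def test_two_identical_residues_double(self, model):
        x = np.random.default_rng(15).standard_normal((1, 32))
        one = float(model.ba_head(ag.Tensor(x)).data)
        two = float(model.ba_head(ag.Tensor(np.vstack([x, x]))).data)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_matches_loop_oracle(self, model):
        x = np.random.default_rng(16).standard_normal((9, 32))
        got = float(model.ba_head(ag.Tensor(x)).data)
        P = model.params
        total = 0.0
        for i in range(9):
            row = x[i]
            mu = row.mean()
            var = ((row - mu) ** 2).mean()
            hn = (row - mu) / np.sqrt(var + 1e-5) * P["ba.ln.g"].data \
                + P["ba.ln.b"].data
            h = np.maximum(hn @ P["ba.h.W"].data + P["ba.h.b"].data, 0)
            total += float((h @ P["ba.out.W"].data + P["ba.out.b"].data)[0])
        assert got == pytest.approx(total, abs=1e-6)


class TestPredict:
    def test_deterministic_and_batch_equal(self, bundle):
        m1 = nn.Model(nn.ModelConfig(seed=4))
        m2 = nn.Model(nn.ModelConfig(seed=4))
        r1 = m1.predict(bundle)
        r2 = m2.predict(bundle)
        assert r1.score == r2.score
        assert np.array_equal(r1.atoms, r2.atoms)
        batch = m1.predict_batch([bundle] * 5, batch_size=64)
        assert all(b.score == r1.score for b in batch)

    def test_atoms_equal_geometry_placement(self, bundle):
        m = nn.Model(nn.ModelConfig(seed=4))
        res = m.predict(bundle)
        coords, mask = geo.place_atoms(res.frames, res.torsions, bundle.pep_seq)
        assert np.abs(coords - res.atoms)[mask].max() <= 1e-4

    def test_binder_flag_consistent(self, bundle):
        m = nn.Model(nn.ModelConfig(seed=4))
        res = m.predict(bundle)
        assert res.binder == (res.score > dp.BINDER_SCORE_THRESHOLD)

    def test_attention_export_shape(self, bundle):
        m = nn.Model(nn.ModelConfig(seed=4))
        res = m.predict(bundle, return_attention=True)
        assert res.attention.shape == (8, 9, len(bundle.mhc_seq))


class TestCheckpoints:
    def test_round_trip(self, bundle, tmp_path):
        m = nn.Model(nn.ModelConfig(seed=7))
        path = tmp_path / "w.npz"
        m.save(path)
        m2 = nn.Model.load(path)
        assert m2.predict(bundle).score == m.predict(bundle).score

    def test_schema_version_checked(self, tmp_path):
        m = nn.Model(nn.ModelConfig(seed=7))
        path = tmp_path / "w.npz"
        m.save(path)
        import json
        data = dict(np.load(path))
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["schema"] = 999
        data["__meta__"] = np.frombuffer(json.dumps(meta).encode(), np.uint8)
        np.savez(path, **data)
        with pytest.raises(ValueError, match="schema"):
            nn.Model.load(path)
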