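"""The four-module attention network.

Module 1 (MHC self IPA) encodes each MHC residue from its amino-acid type
and structural neighborhood: attention logits combine feature dot-products,
a learned per-head bias on the residue-residue proximity matrix, and
invariant point terms computed in the fixed MHC backbone frames.  Module 2
(peptide self attention) mixes peptide residues with relative positional
encoding only.  Module 3 (cross-attention structure) starts every peptide
residue as an identity frame at the groove center and iteratively
cross-attends peptide -> MHC, updating peptide features and composing
quaternion frame updates; after the final block it predicts side-chain and
backbone torsions and places all atoms.  Module 4 (affinity head) sums a
shared per-residue perceptron over peptide positions, making the score
length-agnostic.

Because point terms are either expressed in local frames or depend only on
inter-point distances, the whole network is invariant to a global rigid
motion applied consistently to the MHC frames.

All parameters live in one flat dict of named tensors; initialization is
fully determined by the config seed.  Residual branches end in small-scale
projections (near-identity but symmetry-broken start); the frame-update
heads start at exactly zero, so a freshly built network leaves the peptide
frames at the groove center.  Each output head reads a layer-normalized
copy of the trunk.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import autograd as ag
from . import dataprep as dp
from . import geometry as geo
from . import residues as rc

CHECKPOINT_SCHEMA = 1
_NEG_INF = -1e9


@dataclass(frozen=True)
class ModelConfig:
    width: int = 32                 # feature width (c_s-compatible)
    heads: int = 8
    head_dim: int = 8
    points: int = 4                 # query/key points per head
    mhc_blocks: int = 2
    pep_blocks: int = 2             # peptide self-attention iterations
    cross_blocks: int = 4
    ba_hidden: int = 32             # affinity head hidden width
    max_pep_len: int = 15           # relative-offset table half-range
    trans_scale: float = 10.0       # A per unit of predicted translation
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self):
        if min(self.width, self.heads, self.head_dim, self.points,
               self.ba_hidden) < 1:
            raise ValueError("all widths must be positive")
        if self.pep_blocks < 1 or self.cross_blocks < 0 or self.mhc_blocks < 0:
            raise ValueError("bad block counts")


@dataclass
class PredictionResult:
    entry_id: str
    score: float
    binder: bool
    frames: list                      # geometry.Frame per peptide residue
    torsions: geo.TorsionSet
    atoms: np.ndarray                 # (r_i, 14, 3)
    atom_mask: np.ndarray
    attention: np.ndarray | None = None   # (heads, r_i, r_j) final block


def _layer_norm(x: ag.Tensor, g: ag.Tensor, b: ag.Tensor) -> ag.Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=-1, keepdims=True)
    return (x - mu) / (var + 1e-5).sqrt() * g + b


class Model:
    """The network: parameters plus the four module forward passes."""

    def __init__(self, config: ModelConfig = ModelConfig()):
        self.config = config
        self.params: dict[str, ag.Tensor] = {}
        self._rng = np.random.default_rng(config.seed)
        c, H, dh, P = config.width, config.heads, config.head_dim, config.points
        self._embed("mhc_embed", dp.C_S_DEFAULT, c)
        self._embed("pep_embed", dp.C_S_DEFAULT, c)
        for b in range(config.mhc_blocks):
            self._ipa_block(f"mhc{b}.", proximity=True)
        for b in range(config.pep_blocks):
            p = f"pep{b}."
            self._linear(p + "q", c, H * dh)
            self._linear(p + "k", c, H * dh)
            self._linear(p + "v", c, H * dh)
            self._param(p + "relpos",
                        0.02 * self._rng.standard_normal(
                            (2 * config.max_pep_len - 1, H)))
            self._linear(p + "out", H * dh, c, small=True)
            self._ln(p + "ln1", c)
            self._mlp(p + "mlp", c)
        for b in range(config.cross_blocks):
            p = f"cross{b}."
            self._ipa_block(p, proximity=False)
            self._ln(p + "ln_head", c)
            self._linear(p + "frame_update", c, 6, zero=True)
        self._ln("torsion.ln", c)
        self._linear("torsion.h", c, c)
        W = np.zeros((c, 2 * rc.N_TORSIONS))
        bias = np.tile([0.0, 1.0], rc.N_TORSIONS)
        bias[2 * 2 + 1] = -1.0      # omega starts trans (cos = -1)
        self._param("torsion.out.W", W)
        self._param("torsion.out.b", bias)
        self._ln("ba.ln", c)
        self._linear("ba.h", c, config.ba_hidden)
        self._linear("ba.out", config.ba_hidden, 1, small=True)

    # -- parameter helpers ---------------------------------------------
    def _param(self, name, data):
        self.params[name] = ag.parameter(
            np.asarray(data, dtype=self.config.dtype)
        )

    def _linear(self, name, din, dout, zero=False, small=False):
        # residual-branch outputs start small so the stack is near-identity
        # yet symmetry-broken; structure heads start exactly at zero so the
        # initial peptide sits at the groove center
        scale = 0.0 if zero else (0.1 if small else 1.0) * np.sqrt(1.0 / din)
        self._param(name + ".W", scale * self._rng.standard_normal((din, dout)))
        self._param(name + ".b", np.zeros(dout))

    def _embed(self, name, din, dout):
        self._linear(name, din, dout)

    def _ln(self, name, c):
        self._param(name + ".g", np.ones(c))
        self._param(name + ".b", np.zeros(c))

    def _mlp(self, name, c):
        self._linear(name + ".fc1", c, 2 * c)
        self._linear(name + ".fc2", 2 * c, c, small=True)
        self._ln(name + ".ln", c)

    def _ipa_block(self, prefix, proximity):
        cfg = self.config
        c, H, dh, P = cfg.width, cfg.heads, cfg.head_dim, cfg.points
        self._linear(prefix + "q", c, H * dh)
        self._linear(prefix + "k", c, H * dh)
        self._linear(prefix + "v", c, H * dh)
        self._linear(prefix + "qp", c, H * P * 3)
        self._linear(prefix + "kp", c, H * P * 3)
        self._param(prefix + "gamma", np.zeros(H))
        if proximity:
            self._param(prefix + "prox_w", np.ones(H))
        self._linear(prefix + "out", H * (dh + 4 * P), c, small=True)
        self._ln(prefix + "ln1", c)
        self._mlp(prefix + "mlp", c)

    def _lin(self, name, x):
        return x @ self.params[name + ".W"] + self.params[name + ".b"]

    def _apply_mlp(self, name, x):
        h = _layer_norm(x, self.params[name + ".ln.g"], self.params[name + ".ln.b"])
        return x + self._lin(name + ".fc2", self._lin(name + ".fc1", h).relu())

    # -- attention machinery -------------------------------------------
    def _heads(self, x, n):
        r = x.shape[0]
        H = self.config.heads
        return x.reshape(r, H, n).transpose(1, 0, 2)      # (H, r, n)

    def _points_global(self, raw, rot, trans):
        """(r, H*P*3) point features -> global coordinates (r, H, P, 3)."""
        r = raw.shape[0]
        H, P = self.config.heads, self.config.points
        pts = raw.reshape(r, H * P, 3)
        if isinstance(rot, ag.Tensor) or isinstance(trans, ag.Tensor):
            g = (ag.astensor(rot) @ pts.transpose(0, 2, 1)).transpose(0, 2, 1)
            g = g + ag.astensor(trans).reshape(r, 1, 3)
        else:
            g = (ag.Tensor(rot) @ pts.transpose(0, 2, 1)).transpose(0, 2, 1)
            g = g + ag.Tensor(trans.reshape(r, 1, 3))
        return g.reshape(r, H, P, 3)

    def _ipa(self, prefix, q_feats, kv_feats, q_rot, q_trans, kv_rot, kv_trans,
             mask=None, proximity=None, return_attention=False):
        """Shared invariant-point attention.  ``q_*``/``kv_*`` frames may be
        constants (MHC) or tensors (current peptide frames)."""
        cfg = self.config
        H, dh, P = cfg.heads, cfg.head_dim, cfg.points
        r_q, r_k = q_feats.shape[0], kv_feats.shape[0]
        q = self._heads(self._lin(prefix + "q", q_feats), dh)      # (H, rq, dh)
        k = self._heads(self._lin(prefix + "k", kv_feats), dh)
        v = self._heads(self._lin(prefix + "v", kv_feats), dh)
        logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))  # (H, rq, rk)
        if proximity is not None:
            w = self.params[prefix + "prox_w"].reshape(H, 1, 1)
            logits = logits + w * ag.Tensor(proximity[None, :, :])
        qg = self._points_global(self._lin(prefix + "qp", q_feats), q_rot, q_trans)
        kg = self._points_global(self._lin(prefix + "kp", kv_feats), kv_rot, kv_trans)
        # squared point distances via |a|^2 + |b|^2 - 2 a.b, batched per
        # (head, point) pair to avoid 5-D temporaries
        qhp = qg.reshape(r_q, H * P, 3).transpose(1, 0, 2)         # (HP, rq, 3)
        khp = kg.reshape(r_k, H * P, 3).transpose(1, 0, 2)
        q2 = (qhp * qhp).sum(axis=-1)                              # (HP, rq)
        k2 = (khp * khp).sum(axis=-1)
        dots = qhp @ khp.transpose(0, 2, 1)                        # (HP, rq, rk)
        d2 = q2.reshape(H * P, r_q, 1) + k2.reshape(H * P, 1, r_k) - 2.0 * dots
        d2 = d2.reshape(H, P, r_q, r_k).sum(axis=1)                # (H, rq, rk)
        gamma = self.params[prefix + "gamma"].exp().reshape(H, 1, 1)
        wc = np.sqrt(2.0 / (9.0 * P))
        logits = logits - (gamma * wc * 0.5) * d2
        if mask is not None:
            bias = np.where(np.asarray(mask, bool), 0.0, _NEG_INF)
            logits = logits + ag.Tensor(bias[None, None, :])
        att = ag.softmax(logits, axis=-1)                          # (H, rq, rk)
        o = (att @ v).transpose(1, 0, 2).reshape(r_q, H * dh)
        # attended global points, mapped back to the query frames
        kg_flat = kg.reshape(r_k, H, P * 3).transpose(1, 0, 2)     # (H, rk, P3)
        og = (att @ kg_flat).transpose(1, 0, 2).reshape(r_q, H * P, 3)
        if isinstance(q_rot, ag.Tensor) or isinstance(q_trans, ag.Tensor):
            local = (og - ag.astensor(q_trans).reshape(r_q, 1, 3)) @ ag.astensor(q_rot)
        else:
            local = (og - ag.Tensor(q_trans.reshape(r_q, 1, 3))) @ ag.Tensor(q_rot)
        norms = ((local * local).sum(axis=-1) + 1e-8).sqrt()       # (rq, H*P)
        feat = ag.concat([o, local.reshape(r_q, H * P * 3), norms], axis=1)
        update = self._lin(prefix + "out", feat)
        if return_attention:
            return update, att
        return update

    # -- the four modules ----------------------------------------------
    def mhc_self_ipa(self, mhc_feats, mhc_rot, mhc_trans, proximity, mask=None):
        """Module 1: returns updated MHC features (r_j, width)."""
        x = ag.astensor(mhc_feats)
        if x.shape[0] != proximity.shape[0]:
            raise ValueError("features / proximity shape mismatch")
        for b in range(self.config.mhc_blocks):
            p = f"mhc{b}."
            h = _layer_norm(x, self.params[p + "ln1.g"], self.params[p + "ln1.b"])
            x = x + self._ipa(p, h, h, mhc_rot, mhc_trans, mhc_rot, mhc_trans,
                              mask=mask, proximity=proximity)
            x = self._apply_mlp(p + "mlp", x)
        return x

    def peptide_self_attention(self, pep_feats):
        """Module 2: returns updated peptide features (r_i, width)."""
        x = ag.astensor(pep_feats)
        r = x.shape[0]
        if r == 0:
            raise ValueError("empty peptide")
        cfg = self.config
        H, dh = cfg.heads, cfg.head_dim
        offs = np.clip(
            np.arange(r)[:, None] - np.arange(r)[None, :] + cfg.max_pep_len - 1,
            0, 2 * cfg.max_pep_len - 2,
        )
        for b in range(cfg.pep_blocks):
            p = f"pep{b}."
            h = _layer_norm(x, self.params[p + "ln1.g"], self.params[p + "ln1.b"])
            q = self._heads(self._lin(p + "q", h), dh)
            k = self._heads(self._lin(p + "k", h), dh)
            v = self._heads(self._lin(p + "v", h), dh)
            rel = self.params[p + "relpos"][offs]                 # (r, r, H)
            logits = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
            logits = logits + rel.transpose(2, 0, 1)
            att = ag.softmax(logits, axis=-1)
            o = (att @ v).transpose(1, 0, 2).reshape(r, H * dh)
            x = x + self._lin(p + "out", o)
            x = self._apply_mlp(p + "mlp", x)
        return x

    def cross_attention_structure(
        self, pep_feats, mhc_feats, mhc_rot, mhc_trans, mask,
        return_attention=False,
    ):
        """Module 3: peptide feature refinement + structure prediction.

        Peptide frames start as identities at the groove center; each block
        composes a predicted quaternion/translation update.  Returns
        ``(pep_feats, rot, trans, sincos, attention)`` as tensors.
        """
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("all MHC residues are masked out")
        x = ag.astensor(pep_feats)
        r = x.shape[0]
        dt = self.config.dtype
        rot = ag.Tensor(np.broadcast_to(np.eye(3, dtype=dt), (r, 3, 3)).copy())
        trans = ag.Tensor(np.zeros((r, 3), dtype=dt))
        att = None
        for b in range(self.config.cross_blocks):
            p = f"cross{b}."
            h = _layer_norm(x, self.params[p + "ln1.g"], self.params[p + "ln1.b"])
            upd, att = self._ipa(
                p, h, ag.astensor(mhc_feats), rot, trans, mhc_rot, mhc_trans,
                mask=mask, return_attention=True,
            )
            x = x + upd
            x = self._apply_mlp(p + "mlp", x)
            hn = _layer_norm(x, self.params[p + "ln_head.g"],
                             self.params[p + "ln_head.b"])
            head = self._lin(p + "frame_update", hn)              # (r, 6)
            quat = ag.concat(
                [ag.Tensor(np.ones((r, 1), dtype=dt)), head[:, :3]], axis=1
            )
            rot_u = rotmat_from_quat_t(quat)
            t_u = head[:, 3:] * self.config.trans_scale
            trans = (rot @ t_u.reshape(r, 3, 1)).reshape(r, 3) + trans
            rot = rot @ rot_u
        xt = _layer_norm(x, self.params["torsion.ln.g"], self.params["torsion.ln.b"])
        raw = self._lin("torsion.out", self._lin("torsion.h", xt).relu())
        raw = raw.reshape(r, rc.N_TORSIONS, 2)
        norm = ((raw * raw).sum(axis=-1, keepdims=True) + 1e-8).sqrt()
        sincos = raw / norm
        if return_attention:
            return x, rot, trans, sincos, att
        return x, rot, trans, sincos

    def ba_head(self, pep_feats) -> ag.Tensor:
        """Module 4: sum over residues of a shared two-layer perceptron."""
        x = ag.astensor(pep_feats)
        x = _layer_norm(x, self.params["ba.ln.g"], self.params["ba.ln.b"])
        per_res = self._lin("ba.out", self._lin("ba.h", x).relu())  # (r, 1)
        return per_res.sum()

    # -- full forward ----------------------------------------------------
    def forward(self, bundle: dp.FeatureBundle, return_attention=False):
        """Differentiable forward pass on one record; returns tensors."""
        dt = self.config.dtype
        mhc_feats = self._lin("mhc_embed", ag.Tensor(bundle.mhc_onehot.astype(dt)))
        mrot = bundle.mhc_rot.astype(dt)
        mtrans = bundle.mhc_trans.astype(dt)
        prox = bundle.proximity.astype(dt)
        mhc_feats = self.mhc_self_ipa(mhc_feats, mrot, mtrans, prox,
                                      mask=bundle.cross_mask)
        pep = self._lin("pep_embed", ag.Tensor(bundle.pep_onehot.astype(dt)))
        pep = self.peptide_self_attention(pep)
        pep, rot, trans, sincos, att = self.cross_attention_structure(
            pep, mhc_feats, mrot, mtrans, bundle.cross_mask,
            return_attention=True,
        )
        score = self.ba_head(pep)
        out = {
            "score": score, "rot": rot, "trans": trans, "sincos": sincos,
            "pep_feats": pep,
        }
        if return_attention:
            out["attention"] = att
        return out

    def predict(self, bundle: dp.FeatureBundle,
                return_attention=False) -> PredictionResult:
        """Inference on one record; places all atoms."""
        out = self.forward(bundle, return_attention=return_attention)
        aatype = rc.seq_to_indices(bundle.pep_seq)
        atoms = geo.atoms_from_frames_torsions_t(
            ag.Tensor(out["rot"].data.astype(np.float64)),
            ag.Tensor(out["trans"].data.astype(np.float64)),
            ag.Tensor(out["sincos"].data.astype(np.float64)),
            aatype,
        ).data
        exists = rc.stacked_layouts()["exists"][aatype]
        consts = rc.stacked_layouts()
        defined = np.ones((len(aatype), rc.N_TORSIONS), dtype=bool)
        defined[:, 3:] = consts["chi_defined"][aatype]
        score = float(out["score"].data)
        frames = [
            geo.Frame(geo.matrix_to_quat(out["rot"].data[i].astype(np.float64)),
                      out["trans"].data[i])
            for i in range(len(aatype))
        ]
        return PredictionResult(
            entry_id=bundle.entry_id,
            score=score,
            binder=bool(score > dp.BINDER_SCORE_THRESHOLD),
            frames=frames,
            torsions=geo.TorsionSet.from_sincos(
                out["sincos"].data.astype(np.float64), defined
            ),
            atoms=np.where(exists[..., None], atoms, 0.0),
            atom_mask=exists,
            attention=out["attention"].data if return_attention else None,
        )

    def predict_batch(self, bundles, batch_size: int = 64):
        """Batch inference; per-record results are identical to single-record
        calls by construction (records are independent)."""
        return [self.predict(b) for b in bundles]

    # -- checkpoints -----------------------------------------------------
    def state_dict(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict) -> None:
        for k, v in self.params.items():
            if k not in state:
                raise ValueError(f"checkpoint missing parameter {k!r}")
            if state[k].shape != v.data.shape:
                raise ValueError(f"shape mismatch for {k!r}")
            v.data = state[k].astype(self.config.dtype)

    def save(self, path) -> None:
        meta = json.dumps({"schema": CHECKPOINT_SCHEMA,
                           "config": asdict(self.config)})
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **self.state_dict())

    @classmethod
    def load(cls, path) -> "Model":
        with np.load(path) as fh:
            meta = json.loads(bytes(fh["__meta__"]).decode())
            if meta.get("schema") != CHECKPOINT_SCHEMA:
                raise ValueError(
                    f"incompatible checkpoint schema {meta.get('schema')} "
                    f"(expected {CHECKPOINT_SCHEMA})"
                )
            model = cls(ModelConfig(**meta["config"]))
            model.load_state_dict({k: fh[k] for k in fh.files
                                   if k != "__meta__"})
        return model


def rotmat_from_quat_t(q: ag.Tensor) -> ag.Tensor:
    """Differentiable rotation matrices from (possibly unnormalized)
    quaternions (..., 4); normalized internally."""
    q = ag.astensor(q)
    n2 = (q * q).sum(axis=-1, keepdims=True)
    q = q / (n2 + 1e-12).sqrt()
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    rows = [
        ag.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                  2 * (x * z + w * y)], axis=-1),
        ag.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                  2 * (y * z - w * x)], axis=-1),
        ag.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                  1 - 2 * (x * x + y * y)], axis=-1),
    ]
    return ag.stack(rows, axis=-2)
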