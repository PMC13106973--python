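"""Naive reference implementations used as independent oracles in tests.

These deliberately re-derive the attention computations with explicit
Python loops over residues, heads and points, reading the same parameter
dict as the vectorized network code but sharing none of its array
machinery.
"""

import numpy as np


def naive_ipa(model, prefix, q_feats, kv_feats, q_rot, q_trans, kv_rot,
              kv_trans, mask=None, proximity=None):
    """Double-loop invariant-point-attention update."""
    P = model.params
    cfg = model.config
    H, dh, Pn = cfg.heads, cfg.head_dim, cfg.points
    rq, rk = len(q_feats), len(kv_feats)

    def lin(name, x):
        return x @ P[name + ".W"].data + P[name + ".b"].data

    q = lin(prefix + "q", q_feats).reshape(rq, H, dh)
    k = lin(prefix + "k", kv_feats).reshape(rk, H, dh)
    v = lin(prefix + "v", kv_feats).reshape(rk, H, dh)
    qp = lin(prefix + "qp", q_feats).reshape(rq, H, Pn, 3)
    kp = lin(prefix + "kp", kv_feats).reshape(rk, H, Pn, 3)
    gamma = np.exp(P[prefix + "gamma"].data)
    wc = np.sqrt(2.0 / (9.0 * Pn))
    out = np.zeros((rq, P[prefix + "out.W"].data.shape[1]))
    for i in range(rq):
        feats = []
        for h in range(H):
            logits = np.empty(rk)
            for j in range(rk):
                s = q[i, h] @ k[j, h] / np.sqrt(dh)
                if proximity is not None:
                    s += P[prefix + "prox_w"].data[h] * proximity[i, j]
                d2 = 0.0
                for p in range(Pn):
                    gq = q_rot[i] @ qp[i, h, p] + q_trans[i]
                    gk = kv_rot[j] @ kp[j, h, p] + kv_trans[j]
                    d2 += ((gq - gk) ** 2).sum()
                s -= 0.5 * gamma[h] * wc * d2
                if mask is not None and not mask[j]:
                    s = -1e9
                logits[j] = s
            w = np.exp(logits - logits.max())
            w /= w.sum()
            o = sum(w[j] * v[j, h] for j in range(rk))
            opts = np.zeros((Pn, 3))
            for p in range(Pn):
                for j in range(rk):
                    opts[p] += w[j] * (kv_rot[j] @ kp[j, h, p] + kv_trans[j])
            local = (opts - q_trans[i]) @ q_rot[i]
            norms = np.sqrt((local ** 2).sum(-1) + 1e-8)
            feats.append((o, local, norms))
        out[i] = lin(
            prefix + "out",
            np.concatenate([np.concatenate([f[0] for f in feats]),
                            np.concatenate([f[1].reshape(-1) for f in feats]),
                            np.concatenate([f[2] for f in feats])]))
    return out


def naive_peptide_blocks(model, x):
    """Loop reimplementation of the full peptide self-attention stack."""
    P = model.params
    cfg = model.config
    H, dh = cfg.heads, cfg.head_dim
    r = len(x)
    h0 = np.array(x, dtype=np.float64)

    def ln(name, y):
        g, b = P[name + ".g"].data, P[name + ".b"].data
        mu = y.mean(-1, keepdims=True)
        var = ((y - mu) ** 2).mean(-1, keepdims=True)
        return (y - mu) / np.sqrt(var + 1e-5) * g + b

    for blk in range(cfg.pep_blocks):
        p = f"pep{blk}."
        hn = ln(p + "ln1", h0)
        q = (hn @ P[p + "q.W"].data + P[p + "q.b"].data).reshape(r, H, dh)
        k = (hn @ P[p + "k.W"].data + P[p + "k.b"].data).reshape(r, H, dh)
        v = (hn @ P[p + "v.W"].data + P[p + "v.b"].data).reshape(r, H, dh)
        upd = np.zeros((r, H * dh))
        for i in range(r):
            per_head = []
            for hh in range(H):
                logits = np.array([
                    q[i, hh] @ k[j, hh] / np.sqrt(dh)
                    + P[p + "relpos"].data[
                        np.clip(i - j + cfg.max_pep_len - 1, 0,
                                2 * cfg.max_pep_len - 2), hh]
                    for j in range(r)
                ])
                w = np.exp(logits - logits.max())
                w /= w.sum()
                per_head.append(sum(w[j] * v[j, hh] for j in range(r)))
            upd[i] = np.concatenate(per_head)
        h0 = h0 + upd @ P[p + "out.W"].data + P[p + "out.b"].data
        hn2 = ln(p + "mlp.ln", h0)
        a1 = np.maximum(hn2 @ P[p + "mlp.fc1.W"].data
                        + P[p + "mlp.fc1.b"].data, 0)
        h0 = h0 + a1 @ P[p + "mlp.fc2.W"].data + P[p + "mlp.fc2.b"].data
    return h0


def random_torsion_nine_mer(rng, sequence=None):
    """A random ideal-geometry 9-mer built directly from torsions."""
    from pmhcnet import geometry as geo
    from pmhcnet import residues as rc

    seq = sequence or "".join(rng.choice(list(rc.AA1_ORDER), 9))
    r = len(seq)
    phi = rng.uniform(-150, -60, r)
    psi = rng.uniform(100, 160, r)
    omega = np.full(r, 180.0)
    frames = geo.backbone_frames_from_torsions(seq, phi, psi, omega)
    aatype = rc.seq_to_indices(seq)
    chi_def = rc.stacked_layouts()["chi_defined"][aatype]
    angles = np.zeros((r, 7))
    defined = np.zeros((r, 7), dtype=bool)
    angles[:, 0], angles[:, 1], angles[:, 2] = phi, psi, omega
    defined[:, :3] = True
    defined[0, 0] = defined[0, 2] = False
    angles[:, 3:] = np.where(chi_def, rng.uniform(-180, 180, (r, 4)), 0.0)
    defined[:, 3:] = chi_def
    tors = geo.TorsionSet(angles, defined)
    coords, mask = geo.place_atoms(frames, tors, seq)
    return seq, frames, tors, coords, mask
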