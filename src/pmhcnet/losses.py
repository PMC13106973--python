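"""Training loss terms: affinity, frame-aligned point error, torsion angles
and geometric violations.

All terms accept either plain arrays or autograd tensors for the predicted
quantities; ground truths are constants.  Numerical conventions follow the
fine-tuning practice this family of structure networks inherits: FAPE
clamped at 10 A and scaled by 10 A; flat-bottom violation penalties that
vanish within 12 sigma of literature bond lengths/angles; clash penalty on
non-bonded pairs closer than the van der Waals sum minus a 1.5 A tolerance.
All constants live in :class:`LossConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import residues as rc

# Engh & Huber spreads used by the flat-bottom penalties
SIGMA_BOND_C_N = 0.014          # Angstrom
SIGMA_ANGLE = 2.0               # degrees, generic backbone angle spread


@dataclass(frozen=True)
class LossConfig:
    fape_clamp: float = 10.0            # A
    fape_scale: float = 10.0            # A
    bond_tolerance_sigmas: float = 12.0
    clash_tolerance: float = 1.5        # A subtracted from the vdW sum
    w_ba: float = 1.0
    w_fape: float = 1.0
    w_torsion: float = 1.0
    w_violation: float = 1.0


@dataclass
class LossReport:
    """Per-term loss values; ``total`` sums the enabled, weighted terms."""

    ba_loss: float = 0.0
    fape: float = 0.0
    torsion_loss: float = 0.0
    violation_bond_length: float = 0.0
    violation_bond_angle: float = 0.0
    violation_clash: float = 0.0
    enabled: dict = field(default_factory=lambda: {
        "ba": True, "fape": True, "torsion": True, "violation": False,
    })
    total: float = 0.0


def _as_t(x) -> ag.Tensor:
    return x if isinstance(x, ag.Tensor) else ag.Tensor(np.asarray(x, dtype=np.float64))


def ba_loss(pred, true) -> ag.Tensor:
    """Mean squared difference between predicted and true rescaled
    affinities (scalars or batches)."""
    p = _as_t(pred)
    t = _as_t(true)
    return ((p - t) ** 2.0).mean()


def _smooth_norm(x: ag.Tensor, eps: float = 1e-16) -> ag.Tensor:
    """sqrt(|x|^2 + eps) - sqrt(eps): exactly zero at zero, smooth there,
    asymptotically the Euclidean norm."""
    return ((x * x).sum(axis=-1) + eps).sqrt() - np.sqrt(eps)


def fape(
    pred_rot, pred_trans, pred_atoms,
    true_rot, true_trans, true_atoms,
    atom_mask=None,
    clamp: float = 10.0,
    scale: float = 10.0,
) -> ag.Tensor:
    """Frame-aligned point error over peptide frames and atoms.

    Every atom position is expressed in every residue's local frame on both
    sides; the clamped mean distance, divided by ``scale``, is invariant to
    any global rigid motion applied to either structure.
    """
    pr, pt = _as_t(pred_rot), _as_t(pred_trans)
    pa = _as_t(pred_atoms)
    tr = np.asarray(true_rot, dtype=np.float64)
    tt = np.asarray(true_trans, dtype=np.float64)
    ta = np.asarray(true_atoms, dtype=np.float64)
    if pa.shape != ta.shape:
        raise ValueError("predicted/true atom layouts disagree")
    n_res = pr.shape[0]
    pa_flat = pa.reshape(-1, 3)
    ta_flat = ta.reshape(-1, 3)
    if atom_mask is None:
        atom_mask = np.ones(len(ta_flat), dtype=bool)
    else:
        atom_mask = np.asarray(atom_mask, dtype=bool).reshape(-1)
    # local coordinates: (frames, atoms, 3)
    local_p = (pa_flat.reshape(1, -1, 3) - pt.reshape(n_res, 1, 3)) @ pr
    local_t = (ta_flat[None, :, :] - tt[:, None, :]) @ tr
    d = _smooth_norm(local_p - ag.Tensor(local_t))
    d = ag.clamp_max(d, clamp)
    d = d[:, atom_mask]
    return d.mean() / scale


def torsion_loss(pred_sincos, true_sincos, defined=None) -> ag.Tensor:
    """Mean squared distance between predicted and true (sin, cos) pairs
    over defined angles; periodic by construction (theta and theta + 360
    are the same point on the unit circle)."""
    p = _as_t(pred_sincos)
    t = np.asarray(true_sincos, dtype=np.float64)
    if defined is None:
        defined = np.ones(t.shape[:-1], dtype=bool)
    defined = np.asarray(defined, dtype=bool)
    sq = ((p - ag.Tensor(t)) ** 2.0).sum(axis=-1)
    if not defined.any():
        return sq.sum() * 0.0
    return sq[defined].mean()


def torsion_loss_degrees(pred: "object", true: "object") -> float:
    """Convenience wrapper over two TorsionSets (must agree on definedness)."""
    if not np.array_equal(pred.defined, true.defined):
        raise ValueError("definedness flags of the two TorsionSets disagree")
    return float(
        torsion_loss(pred.sincos(), true.sincos(), true.defined).data
    )


def violation_losses(
    atoms,
    aatype: np.ndarray,
    atom_mask: np.ndarray | None = None,
    config: LossConfig = LossConfig(),
):
    """Flat-bottom penalties for abnormal bond lengths, bond angles and
    atomic clashes; zero on ideal, clash-free geometry.

    Bond terms cover the inter-residue peptide bond C(i)-N(i+1) and the
    flanking backbone angles CA-C-N and C-N-CA (in cosine space); the clash
    term penalizes inter-residue non-bonded pairs (the peptide-bond pair
    excluded) closer than the vdW sum minus ``clash_tolerance``.  Returns a
    dict with tensors ``bond_length``, ``bond_angle``, ``clash``.
    """
    a = _as_t(atoms)
    r = a.shape[0]
    consts = rc.stacked_layouts()
    if atom_mask is None:
        atom_mask = consts["exists"][aatype]
    tol = config.bond_tolerance_sigmas

    zero = ag.Tensor(np.zeros(()))
    if r < 2:
        return {"bond_length": zero, "bond_angle": zero, "clash": zero}

    C = a[:, 2, :]
    N = a[:, 0, :]
    CA = a[:, 1, :]
    d_cn = _smooth_norm(C[:-1, :] - N[1:, :])
    excess = (d_cn - rc.PEPTIDE_BOND_LENGTH) ** 2.0
    excess = (excess + 1e-16).sqrt() - (tol * SIGMA_BOND_C_N)
    bond_length = (excess.relu()).mean()

    def cos_angle(p, q, s):
        u = p - q
        v = s - q
        return (u * v).sum(axis=-1) / (
            _smooth_norm(u, 1e-12) * _smooth_norm(v, 1e-12)
        )

    sig_cos = np.radians(SIGMA_ANGLE)  # small-angle: d(cos) ~ sin * d(theta)
    terms = []
    for cosv, ideal in (
        (cos_angle(CA[:-1, :], C[:-1, :], N[1:, :]), rc.ANGLE_CA_C_N),
        (cos_angle(C[:-1, :], N[1:, :], CA[1:, :]), rc.ANGLE_C_N_CA),
    ):
        ideal_cos = np.cos(np.radians(ideal))
        band = tol * sig_cos * abs(np.sin(np.radians(ideal)))
        dev = ((cosv - ideal_cos) ** 2.0 + 1e-16).sqrt() - band
        terms.append(dev.relu().mean())
    bond_angle = (terms[0] + terms[1]) * 0.5

    # clash term: all inter-residue heavy-atom pairs except the bonded C-N
    radii_tab = np.zeros((20, rc.N_ATOM_SLOTS))
    for k, aa3 in enumerate(rc.AA3_ORDER):
        lay = rc.get_layout(aa3)
        for s, n in enumerate(lay.atom14_names):
            radii_tab[k, s] = rc.VDW_RADII[rc.element_of(n)]
    radii = radii_tab[aatype]                       # (r, 14)
    flat = a.reshape(-1, 3)
    n_at = r * rc.N_ATOM_SLOTS
    valid = atom_mask.reshape(-1)
    res_of = np.repeat(np.arange(r), rc.N_ATOM_SLOTS)
    pair_ok = (
        valid[:, None] & valid[None, :]
        & (res_of[:, None] != res_of[None, :])
    )
    pair_ok &= np.triu(np.ones((n_at, n_at), dtype=bool), 1)
    # exclude the peptide bond C(i) - N(i+1)
    for i in range(r - 1):
        pair_ok[i * rc.N_ATOM_SLOTS + 2, (i + 1) * rc.N_ATOM_SLOTS + 0] = False
        pair_ok[(i + 1) * rc.N_ATOM_SLOTS + 0, i * rc.N_ATOM_SLOTS + 2] = False
    ii, jj = np.nonzero(pair_ok)
    if len(ii) == 0:
        clash = zero
    else:
        d = _smooth_norm(flat[ii, :] - flat[jj, :], 1e-12)
        rsum = radii.reshape(-1)[ii] + radii.reshape(-1)[jj]
        overlap = (ag.Tensor(rsum - config.clash_tolerance) - d).relu()
        clash = overlap.sum() / float(r)
    return {"bond_length": bond_length, "bond_angle": bond_angle, "clash": clash}


def total_loss(report: LossReport, config: LossConfig = LossConfig()) -> float:
    t = 0.0
    if report.enabled.get("ba", False):
        t += config.w_ba * report.ba_loss
    if report.enabled.get("fape", False):
        t += config.w_fape * report.fape
    if report.enabled.get("torsion", False):
        t += config.w_torsion * report.torsion_loss
    if report.enabled.get("violation", False):
        t += config.w_violation * (
            report.violation_bond_length
            + report.violation_bond_angle
            + report.violation_clash
        )
    report.total = t
    return t
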