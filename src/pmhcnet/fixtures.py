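"""Deterministic synthetic pMHC-like fixtures.

Real class I grooves are two long helices over a beta-sheet floor; the toy
scaffold here reproduces that topology at reduced size — two 14-residue
helices flanking a 4-strand sheet floor, concave side up, groove center at
the origin — with ideal geometry throughout, so the full pipeline (feature
extraction, attention, training, structural QC) can run with no downloads.
These are test scaffolds, not models of any real allele.

Affinity labels follow a stated deterministic rule driven by the peptide
anchor positions 2 and 9 (the positions that bury into the P2/P9 pockets of
real grooves): the rescaled target is an affine function of the mean
hydropathy of the two anchor residues, mapped back to a Kd through the
1 - log50000 transform.  The rule is linear in the anchor one-hots, hence
learnable by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from . import dataprep as dp
from . import geometry as geo
from . import residues as rc

# Kyte-Doolittle hydropathy, rescaled to [0, 1]; drives the toy label rule.
_KD_HYDROPATHY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}
ANCHOR_POSITIONS = (2, 9)       # 1-based, the P2/P9 anchors
LABEL_BASE = 0.25
LABEL_SCALE = 0.6

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)
COIL_PHI_PSI = (-120.0, 130.0)

# residues used for scaffold sequences: short side chains only, so the
# groove walls cannot reach the threaded peptide; the sheet floor uses the
# shortest ones since peptide side chains point down into it
_HELIX_ALPHABET = "AST"
_SHEET_ALPHABET = "AAG"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic generator; same spec -> identical output."""

    seed: int = 0
    peptide_length: int = 9
    helix_length: int = 14
    strand_length: int = 5
    n_strands: int = 4
    helix_y: float = 9.0
    helix_z: float = 4.5
    sheet_z: float = -7.5
    peptide_z: float = 0.3
    torsion_preset: str = "coil"    # helix | strand | coil
    torsion_jitter: float = 6.0     # degrees, uniform half-width
    noise_sigma: float = 0.0        # Angstrom, coordinate noise

    @property
    def mhc_size(self) -> int:
        return 2 * self.helix_length + self.n_strands * self.strand_length


def _preset_phi_psi(preset: str):
    return {
        "helix": HELIX_PHI_PSI,
        "strand": STRAND_PHI_PSI,
        "coil": COIL_PHI_PSI,
    }[preset]


def _segment(seq, phi_psi, rng, jitter=0.0):
    """Ideal-geometry chain segment with trans peptide bonds and -60/180-ish
    side-chain rotamers; returns (frames, torsions)."""
    r = len(seq)
    phi0, psi0 = phi_psi
    phi = np.full(r, phi0) + (rng.uniform(-jitter, jitter, r) if jitter else 0.0)
    psi = np.full(r, psi0) + (rng.uniform(-jitter, jitter, r) if jitter else 0.0)
    omega = np.full(r, 180.0)
    frames = geo.backbone_frames_from_torsions(seq, phi, psi, omega)
    aatype = rc.seq_to_indices(seq)
    chi_def = rc.stacked_layouts()["chi_defined"][aatype]
    angles = np.zeros((r, rc.N_TORSIONS))
    defined = np.zeros((r, rc.N_TORSIONS), dtype=bool)
    angles[:, 0], angles[:, 1], angles[:, 2] = phi, psi, omega
    defined[:, :3] = True
    defined[0, 0] = defined[0, 2] = False
    rotamers = np.array([-60.0, 180.0, 60.0])
    chis = rotamers[rng.integers(0, 3, size=(r, 4))] + (
        rng.uniform(-jitter, jitter, (r, 4)) if jitter else 0.0
    )
    angles[:, 3:] = np.where(chi_def, chis, 0.0)
    defined[:, 3:] = chi_def
    return frames, geo.TorsionSet(angles, defined)


def _orient_along_x(coords, mask, target_center):
    """Rigidly move a segment so its CA principal axis lies along +x and its
    CA centroid sits at ``target_center``."""
    ca = coords[:, 1]
    center = ca.mean(axis=0)
    u, _, _ = np.linalg.svd((ca - center).T @ (ca - center))
    axis = u[:, 0]
    if axis[0] < 0:
        axis = -axis
    # rotation taking `axis` to +x (stable even for nearly-aligned axes)
    v = np.cross(axis, [1.0, 0.0, 0.0])
    s = np.linalg.norm(v)
    c = float(axis @ [1.0, 0.0, 0.0])
    if s < 1e-12:
        R = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        R = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = np.where(mask[..., None], (coords - center) @ R.T + target_center, 0.0)
    return out


def _build_segment(seq, phi_psi, rng, target_center, jitter=0.0):
    frames, tors = _segment(seq, phi_psi, rng, jitter)
    coords, mask = geo.place_atoms(frames, tors, seq)
    return _orient_along_x(coords, mask, np.asarray(target_center, float)), mask


def make_toy_mhc(spec: FixtureSpec = FixtureSpec()) -> dp.PMHCComplex:
    """Rigid two-helix + sheet scaffold with a concave groove at the origin.

    The returned complex carries a single-alanine placeholder peptide at the
    groove center (the complex type requires a peptide); callers that need a
    real peptide use :func:`make_toy_complex`.
    """
    rng = np.random.default_rng(spec.seed)
    segs = []
    # two groove helices, antiparallel about the x-axis
    for sign in (+1, -1):
        seq = "".join(rng.choice(list(_HELIX_ALPHABET), spec.helix_length))
        coords, mask = _build_segment(
            seq, HELIX_PHI_PSI, rng, (0.0, sign * spec.helix_y, spec.helix_z)
        )
        segs.append((seq, coords, mask))
    # sheet floor
    width = spec.n_strands - 1
    for k in range(spec.n_strands):
        seq = "".join(rng.choice(list(_SHEET_ALPHABET), spec.strand_length))
        y = (k - width / 2.0) * 3.5
        coords, mask = _build_segment(seq, STRAND_PHI_PSI, rng, (0.0, y, spec.sheet_z))
        segs.append((seq, coords, mask))
    mhc_seq = "".join(s for s, _, _ in segs)
    mhc_coords = np.concatenate([c for _, c, _ in segs])
    mhc_mask = np.concatenate([m for _, _, m in segs])
    lay = rc.get_layout("ALA")
    pep_coords = lay.ideal_atom14[None]
    pep_mask = lay.atom14_exists[None]
    return dp.PMHCComplex(
        f"toy-mhc-{spec.seed}", "TOY", mhc_seq, mhc_coords, mhc_mask,
        "A", pep_coords, pep_mask,
    )


def groove_center(mhc: dp.PMHCComplex) -> np.ndarray:
    """Center of mass of the groove-lining CA atoms (the helix residues)."""
    ca = mhc.mhc_coords[:, 1]
    return ca[np.abs(ca[:, 1]) > 4.0].mean(axis=0)


def _random_peptide(rng, length):
    return "".join(rng.choice(list(rc.AA1_ORDER), length))


def make_toy_complex(
    spec: FixtureSpec = FixtureSpec(),
    peptide: str | None = None,
    mhc: dp.PMHCComplex | None = None,
):
    """A peptide threaded through the toy groove.

    Returns ``(complex, torsions, frames)`` where the torsions and frames
    are exactly those used to place the peptide atoms (before any noise).
    A prebuilt scaffold may be passed to share one MHC across records.
    """
    if mhc is None:
        mhc = make_toy_mhc(spec)
    # separate substream for the peptide so the scaffold stays identical
    prng = np.random.default_rng(spec.seed + 100003)
    pep_seq = peptide or _random_peptide(prng, spec.peptide_length)
    frames, tors, coords, mask = _thread_peptide(pep_seq, spec, mhc, prng)
    if spec.noise_sigma > 0:
        noise = prng.normal(0.0, spec.noise_sigma, coords.shape)
        coords = np.where(mask[..., None], coords + noise, 0.0)
    cx = dp.PMHCComplex(
        f"toy-{spec.seed}-{pep_seq}", "TOY", mhc.mhc_seq, mhc.mhc_coords,
        mhc.mhc_mask, pep_seq, coords, mask,
    )
    return cx, tors, frames


_CHI_GRID = [
    (c1, c2)
    for c1 in (-60.0, 60.0, 180.0, -120.0, 120.0)
    for c2 in (180.0, -60.0, 60.0, -120.0, 120.0)
]


def _thread_peptide(pep_seq, spec, mhc, prng):
    """Backbone from jittered coil torsions, oriented along the groove axis;
    side-chain rotamers chosen greedily (deterministic order) to keep every
    non-excepted atom pair outside van der Waals contact."""
    r = len(pep_seq)
    phi0, psi0 = _preset_phi_psi(spec.torsion_preset)
    j = spec.torsion_jitter
    phi = phi0 + (prng.uniform(-j, j, r) if j else np.zeros(r))
    psi = psi0 + (prng.uniform(-j, j, r) if j else np.zeros(r))
    omega = np.full(r, 180.0)
    bb_frames = geo.backbone_frames_from_torsions(pep_seq, phi, psi, omega)
    aatype = rc.seq_to_indices(pep_seq)
    chi_def = rc.stacked_layouts()["chi_defined"][aatype]
    angles = np.zeros((r, rc.N_TORSIONS))
    defined = np.zeros((r, rc.N_TORSIONS), dtype=bool)
    angles[:, 0], angles[:, 1], angles[:, 2] = phi, psi, omega
    defined[:, :3] = True
    defined[0, 0] = defined[0, 2] = False
    defined[:, 3:] = chi_def
    # orient the backbone (chi placeholders) through the groove
    coords, mask = geo.place_atoms(bb_frames, geo.TorsionSet(angles, defined),
                                   pep_seq)
    coords = _orient_along_x(coords, mask, (0.0, 0.0, spec.peptide_z))
    frames = geo.frames_from_atoms(coords)

    def _radii(seq, amask):
        out = []
        for i, a in enumerate(seq):
            lay = rc.get_layout(rc.AA1_TO_AA3[a])
            out.extend(
                rc.VDW_RADII[rc.element_of(n)]
                for s, n in enumerate(lay.atom14_names)
                if amask[i, s]
            )
        return np.array(out)

    mhc_atoms = mhc.mhc_coords[mhc.mhc_mask]
    mhc_radii = _radii(mhc.mhc_seq, mhc.mhc_mask)
    # peptide backbone + CB + O per residue are chi-independent
    bb_slots = mask.copy()
    bb_slots[:, 5:] = False
    bb_atoms = [coords[i][bb_slots[i]] for i in range(r)]
    bb_radii = [_radii(pep_seq[i], bb_slots[i][None]) for i in range(r)]
    side_atoms = [np.zeros((0, 3)) for _ in range(r)]
    side_radii = [np.zeros(0) for _ in range(r)]
    chi_jit = prng.uniform(-j, j, (r, 4)) if j else np.zeros((r, 4))
    for _sweep in range(2):
        for i in range(r):
            if not chi_def[i].any():
                continue
            # own-residue atoms are excepted pairs; so is the backbone of
            # residues adjacent to a proline side chain
            skip = {i}
            if pep_seq[i] == "P":
                skip |= {i - 1, i + 1}
            obst = np.concatenate(
                [mhc_atoms]
                + [bb_atoms[k] for k in range(r) if k not in skip]
                + [side_atoms[k] for k in range(r) if k != i]
            )
            obst_r = np.concatenate(
                [mhc_radii]
                + [bb_radii[k] for k in range(r) if k not in skip]
                + [side_radii[k] for k in range(r) if k != i]
            )
            lay = rc.get_layout(rc.AA1_TO_AA3[pep_seq[i]])
            cand_r = np.zeros(rc.N_ATOM_SLOTS - 5)
            for s, n in enumerate(lay.atom14_names[5:]):
                cand_r[s] = rc.VDW_RADII[rc.element_of(n)]
            def try_grid(grid, best=None):
                for c1, c2 in grid:
                    cand = np.array([c1, c2, 180.0, 180.0]) + chi_jit[i]
                    trial = angles[i].copy()
                    trial[3:] = np.where(chi_def[i], cand, 0.0)
                    co_i, m_i = geo.place_atoms(
                        [frames[i]],
                        geo.TorsionSet(trial[None], defined[i][None]),
                        pep_seq[i],
                    )
                    side = co_i[0, 5:][m_i[0, 5:]]
                    if len(side) == 0:
                        return best
                    d = np.linalg.norm(
                        side[:, None, :] - obst[None, :, :], axis=-1
                    )
                    limit = cand_r[m_i[0, 5:]][:, None] + obst_r[None, :]
                    # true vdW overlaps first, then a soft crowding penalty
                    n_hard = int((d < limit).sum())
                    gap = d - limit
                    score = float(np.clip(0.4 - gap, 0.0, None).sum())
                    key = (n_hard, score, -float(gap.min()))
                    if best is None or key < best[0]:
                        best = (key, trial, co_i[0], m_i[0])
                return best

            best = try_grid(_CHI_GRID)
            if best is not None and best[0][0] > 0:
                fine = [
                    (c1, c2)
                    for c1 in np.arange(-180.0, 180.0, 30.0)
                    for c2 in np.arange(-180.0, 180.0, 30.0)
                ]
                best = try_grid(fine, best)
            if best is None:
                continue
            angles[i] = best[1]
            side_mask = best[3].copy()
            side_mask[:5] = False
            side_atoms[i] = best[2][side_mask]
            side_radii[i] = cand_r[side_mask[5:]]
    tors = geo.TorsionSet(angles, defined)
    coords, mask = geo.place_atoms(frames, tors, pep_seq)
    return frames, tors, coords, mask


def label_rule(pep_seq: str) -> float:
    """Deterministic Kd (nM) from the anchor residues.

    target = LABEL_BASE + LABEL_SCALE * mean(h at anchors), where h is
    Kyte-Doolittle hydropathy rescaled to [0, 1]; Kd = 50000^(1 - target).
    """
    hs = []
    for pos in ANCHOR_POSITIONS:
        i = min(pos, len(pep_seq)) - 1
        hs.append((_KD_HYDROPATHY[pep_seq[i]] + 4.5) / 9.0)
    target = LABEL_BASE + LABEL_SCALE * float(np.mean(hs))
    return float(50000.0 ** (1.0 - target))


def make_toy_dataset(
    n: int, spec: FixtureSpec = FixtureSpec(), with_structure: bool = True
) -> list[dp.FeatureBundle]:
    """n labeled records over one shared scaffold, deterministic by seed."""
    if n < 1:
        raise ValueError("need n >= 1")
    bundles = []
    seen = set()
    mhc = make_toy_mhc(spec)
    rng = np.random.default_rng(spec.seed + 7)
    shared = None  # label-only records reuse the scaffold featurization
    for k in range(n):
        sub = replace(spec, seed=spec.seed + 1000 + k)
        pep = _random_peptide(rng, spec.peptide_length)
        if with_structure:
            cx, _, _ = make_toy_complex(sub, peptide=pep, mhc=mhc)
            bundle = dp.bundle_from_complex(cx, kd_nM=label_rule(pep))
        else:
            if shared is None:
                shared = dp.bundle_from_complex(mhc, with_structure=False)
            kd = label_rule(pep)
            bundle = dp.FeatureBundle(
                entry_id=f"toy-{sub.seed}-{pep}",
                pep_seq=pep,
                mhc_seq=shared.mhc_seq,
                pep_onehot=dp.one_hot(pep),
                mhc_onehot=shared.mhc_onehot,
                proximity=shared.proximity,
                mhc_rot=shared.mhc_rot,
                mhc_trans=shared.mhc_trans,
                cross_mask=shared.cross_mask,
                affinity=dp.ba_target(kd),
                binder=dp.classify_binder(kd),
            )
        if bundle.entry_id in seen:  # same peptide drawn twice: disambiguate
            bundle.entry_id = f"{bundle.entry_id}-{k}"
        seen.add(bundle.entry_id)
        bundles.append(bundle)
    return bundles
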