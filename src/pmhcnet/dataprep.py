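"""Structure ingestion, reference superposition and featurization.

A peptide-MHC class I record enters as a PDB file with two chains (the MHC
G-domain and the peptide), pre-trimmed to the G-domain.  All structures are
superposed onto a common reference orientation whose binding-groove center
sits at the origin; the network's peptide frames start as identities at the
origin, so a shared orientation is part of the data contract, not a
convenience.

Features per record: one-hot sequences (width ``c_s`` = 32, channels 20-31
reserved), the MHC residue-residue proximity matrix 1/(1 + d_ij) with d_ij
the shortest heavy-atom distance, MHC backbone frames, a cross-attention
mask selecting groove-proximal MHC residues, optional ground-truth peptide
frames/torsions/atoms, and the affinity target 1 - log50000(Kd).  Kd and
IC50 (nM) are treated identically.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import gemmi
import h5py
import numpy as np

from . import geometry as geo
from . import residues as rc

C_S_DEFAULT = 32
BINDER_THRESHOLD_NM = 500.0
CROSS_MASK_CUTOFF = 15.0


# ---------------------------------------------------------------------------
# affinity transform


def ba_target(kd_nM):
    """Rescaled affinity 1 - log50000(Kd); 1 at 1 nM, 0 at 50 uM.

    Accepts scalars or arrays; strictly decreasing in Kd.  Raises on
    non-positive input.
    """
    kd = np.asarray(kd_nM, dtype=np.float64)
    if np.any(kd <= 0):
        raise ValueError("Kd/IC50 must be positive (nM)")
    out = 1.0 - np.log(kd) / math.log(50000.0)
    return float(out) if np.isscalar(kd_nM) else out


def classify_binder(kd_nM) -> bool | np.ndarray:
    """Binder iff measured Kd/IC50 is strictly below 500 nM."""
    kd = np.asarray(kd_nM, dtype=np.float64)
    if np.any(kd <= 0):
        raise ValueError("Kd/IC50 must be positive (nM)")
    out = kd < BINDER_THRESHOLD_NM
    return bool(out) if np.isscalar(kd_nM) else out


BINDER_SCORE_THRESHOLD = ba_target(BINDER_THRESHOLD_NM)


def one_hot(seq: str, width: int = C_S_DEFAULT) -> np.ndarray:
    """One-hot encode a peptide/MHC sequence into (r, width).

    The 20 standard residue types occupy channels 0-19 (alphabetical by full
    name); remaining channels are reserved zeros.
    """
    idx = rc.seq_to_indices(seq)
    if width < 20:
        raise ValueError("one-hot width must be >= 20")
    out = np.zeros((len(idx), width), dtype=np.float64)
    out[np.arange(len(idx)), idx] = 1.0
    return out


# ---------------------------------------------------------------------------
# complexes


@dataclass
class PMHCComplex:
    """A peptide bound to an MHC G-domain, in the fixed atom14 layout."""

    entry_id: str
    allele: str
    mhc_seq: str
    mhc_coords: np.ndarray          # (r_j, 14, 3)
    mhc_mask: np.ndarray            # (r_j, 14) bool
    pep_seq: str
    pep_coords: np.ndarray          # (r_i, 14, 3)
    pep_mask: np.ndarray            # (r_i, 14) bool
    mhc_resnums: np.ndarray = field(default=None)
    pep_resnums: np.ndarray = field(default=None)

    def __post_init__(self):
        self.mhc_coords = np.asarray(self.mhc_coords, dtype=np.float64)
        self.pep_coords = np.asarray(self.pep_coords, dtype=np.float64)
        self.mhc_mask = np.asarray(self.mhc_mask, dtype=bool)
        self.pep_mask = np.asarray(self.pep_mask, dtype=bool)
        if self.mhc_resnums is None:
            self.mhc_resnums = np.arange(1, len(self.mhc_seq) + 1)
        if self.pep_resnums is None:
            self.pep_resnums = np.arange(1, len(self.pep_seq) + 1)
        if len(self.pep_seq) < 1:
            raise ValueError("peptide must have at least one residue")
        for name, coords, mask in (
            ("mhc", self.mhc_coords, self.mhc_mask),
            ("peptide", self.pep_coords, self.pep_mask),
        ):
            if not np.isfinite(coords[mask]).all():
                raise ValueError(f"non-finite coordinates in {name} chain")
            if not mask[:, :3].all():
                bad = np.where(~mask[:, :3].all(axis=1))[0].tolist()
                raise ValueError(f"{name} residues missing backbone atoms: {bad}")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PMHCComplex":
        """Apply a rigid transform to every atom of the complex."""
        return PMHCComplex(
            self.entry_id,
            self.allele,
            self.mhc_seq,
            np.where(self.mhc_mask[..., None],
                     self.mhc_coords @ rotation.T + translation, 0.0),
            self.mhc_mask,
            self.pep_seq,
            np.where(self.pep_mask[..., None],
                     self.pep_coords @ rotation.T + translation, 0.0),
            self.pep_mask,
            self.mhc_resnums,
            self.pep_resnums,
        )


def _chain_to_arrays(chain, label):
    seq, coords, mask, resnums, problems = [], [], [], [], []
    for res in chain:
        if res.name not in rc.AA3_TO_INDEX:
            raise ValueError(f"unknown residue type {res.name!r} in chain {label}")
        lay = rc.get_layout(res.name)
        c = np.zeros((rc.N_ATOM_SLOTS, 3))
        m = np.zeros(rc.N_ATOM_SLOTS, dtype=bool)
        best = {}
        for atom in res:
            name = atom.name
            if name not in lay.atom14_names:
                continue
            # alternate locations: keep the highest-occupancy conformer
            if name in best and atom.occ <= best[name].occ:
                continue
            best[name] = atom
        for name, atom in best.items():
            s = lay.slot(name)
            c[s] = (atom.pos.x, atom.pos.y, atom.pos.z)
            m[s] = True
        if not m[:3].all():
            problems.append(f"{res.name}{res.seqid.num}")
            continue
        seq.append(rc.AA3_TO_AA1[res.name])
        coords.append(c)
        mask.append(m)
        resnums.append(res.seqid.num)
    if problems:
        raise ValueError(
            f"chain {label}: residues missing backbone atoms: {', '.join(problems)}"
        )
    if not seq:
        raise ValueError(f"chain {label} contains no usable residues")
    return "".join(seq), np.array(coords), np.array(mask), np.array(resnums)


def read_pdb(
    path, mhc_chain: str = "M", peptide_chain: str = "P", entry_id: str | None = None,
    allele: str = "",
) -> PMHCComplex:
    """Read a pMHC complex from PDB; chain roles are given by chain ids."""
    st = gemmi.read_structure(os.fspath(path))
    st.setup_entities()
    model = st[0]
    chains = {ch.name: ch for ch in model}
    for want, role in ((mhc_chain, "MHC"), (peptide_chain, "peptide")):
        if want not in chains:
            raise ValueError(
                f"{role} chain {want!r} not found in {path} "
                f"(present: {sorted(chains)})"
            )
    mseq, mco, mma, mrn = _chain_to_arrays(chains[mhc_chain], mhc_chain)
    pseq, pco, pma, prn = _chain_to_arrays(chains[peptide_chain], peptide_chain)
    return PMHCComplex(
        entry_id or os.path.splitext(os.path.basename(os.fspath(path)))[0],
        allele, mseq, mco, mma, pseq, pco, pma, mrn, prn,
    )


def write_pdb(complex: PMHCComplex, path, mhc_chain: str = "M",
              peptide_chain: str = "P") -> None:
    """Write a complex to PDB (coordinates at the format's 1e-3 A precision)."""
    st = gemmi.Structure()
    st.name = complex.entry_id
    model = gemmi.Model("1")
    serial = 1
    for cname, seq, coords, mask, resnums in (
        (mhc_chain, complex.mhc_seq, complex.mhc_coords, complex.mhc_mask,
         complex.mhc_resnums),
        (peptide_chain, complex.pep_seq, complex.pep_coords, complex.pep_mask,
         complex.pep_resnums),
    ):
        chain = gemmi.Chain(cname)
        for i, aa in enumerate(seq):
            lay = rc.get_layout(rc.AA1_TO_AA3[aa])
            res = gemmi.Residue()
            res.name = lay.name
            res.seqid = gemmi.SeqId(int(resnums[i]), " ")
            for s, atom_name in enumerate(lay.atom14_names):
                if not mask[i, s]:
                    continue
                at = gemmi.Atom()
                at.name = atom_name
                at.element = gemmi.Element(rc.element_of(atom_name))
                at.pos = gemmi.Position(*coords[i, s])
                at.occ = 1.0
                at.serial = serial
                serial += 1
                res.add_atom(at)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    with open(os.fspath(path), "w") as fh:
        fh.write(doc)


# ---------------------------------------------------------------------------
# superposition


def _kabsch(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform mapping mobile onto target."""
    cm = mobile.mean(axis=0)
    ct = target.mean(axis=0)
    H = (mobile - cm).T @ (target - ct)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    return R, t


def align_gdomains(seq_a: str, seq_b: str):
    """Global BLOSUM62 alignment; returns paired (index_a, index_b) arrays
    and the fraction of identical aligned positions."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    aln = aligner.align(seq_a, seq_b)[0]
    ia, ib, ident = [], [], 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for da in range(a1 - a0):
            ia.append(a0 + da)
            ib.append(b0 + da)
            ident += seq_a[a0 + da] == seq_b[b0 + da]
    if not ia:
        raise ValueError("sequence alignment produced no aligned positions")
    return np.array(ia), np.array(ib), ident / len(ia)


def superpose_to_reference(
    mobile: PMHCComplex,
    reference: PMHCComplex,
    cutoff: float = 2.0,
    cycles: int = 5,
    min_identity: float = 0.5,
    return_transform: bool = False,
):
    """Superpose a complex onto the reference orientation.

    The rigid transform is fitted on sequence-aligned G-domain CA pairs by
    least squares with iterative outlier rejection (residual > ``cutoff`` A,
    ``cycles`` rounds), then applied to every atom of the complex, peptide
    included.
    """
    ia, ib, identity = align_gdomains(mobile.mhc_seq, reference.mhc_seq)
    if identity < min_identity:
        raise ValueError(
            f"G-domain identity {identity:.0%} below the {min_identity:.0%} floor"
        )
    ca_m = mobile.mhc_coords[ia, 1]
    ca_r = reference.mhc_coords[ib, 1]
    keep = np.ones(len(ia), dtype=bool)
    R, t = _kabsch(ca_m, ca_r)
    for _ in range(cycles):
        resid = np.linalg.norm(ca_m @ R.T + t - ca_r, axis=1)
        new_keep = resid <= cutoff
        if new_keep.sum() < 3:
            raise ValueError("fewer than 3 CA pairs survive outlier rejection")
        if (new_keep == keep).all():
            break
        keep = new_keep
        R, t = _kabsch(ca_m[keep], ca_r[keep])
    out = mobile.transformed(R, t)
    return (out, R, t) if return_transform else out


# ---------------------------------------------------------------------------
# featurization


def proximity_matrix(complex_or_coords, mask: np.ndarray | None = None) -> np.ndarray:
    """MHC residue-pair proximity 1/(1 + d_ij), d_ij the shortest distance
    between heavy atoms of the two residues.  Symmetric, unit diagonal."""
    if isinstance(complex_or_coords, PMHCComplex):
        coords = complex_or_coords.mhc_coords
        mask = complex_or_coords.mhc_mask
    else:
        coords = np.asarray(complex_or_coords, dtype=np.float64)
        if mask is None:
            mask = np.ones(coords.shape[:2], dtype=bool)
    r = coords.shape[0]
    flat = coords.reshape(r * rc.N_ATOM_SLOTS, 3)
    fmask = mask.reshape(-1)
    d2 = ((flat[:, None, :] - flat[None, :, :]) ** 2).sum(-1)
    d2[~fmask, :] = np.inf
    d2[:, ~fmask] = np.inf
    d2 = d2.reshape(r, rc.N_ATOM_SLOTS, r, rc.N_ATOM_SLOTS)
    dmin = np.sqrt(d2.min(axis=(1, 3)))
    np.fill_diagonal(dmin, 0.0)
    return 1.0 / (1.0 + dmin)


def build_cross_mask(
    mhc: PMHCComplex, groove_center=(0.0, 0.0, 0.0), cutoff: float = CROSS_MASK_CUTOFF
) -> np.ndarray:
    """Cross-attention mask: an MHC residue participates iff its nearest
    heavy atom lies within ``cutoff`` A of the groove center."""
    center = np.asarray(groove_center, dtype=np.float64)
    d = np.linalg.norm(mhc.mhc_coords - center, axis=-1)
    d = np.where(mhc.mhc_mask, d, np.inf)
    return d.min(axis=1) <= cutoff


@dataclass
class FeatureBundle:
    """One training/inference record (see module docstring)."""

    entry_id: str
    pep_seq: str
    mhc_seq: str
    pep_onehot: np.ndarray           # (r_i, c_s)
    mhc_onehot: np.ndarray           # (r_j, c_s)
    proximity: np.ndarray            # (r_j, r_j)
    mhc_rot: np.ndarray              # (r_j, 3, 3) backbone frames
    mhc_trans: np.ndarray            # (r_j, 3)
    cross_mask: np.ndarray           # (r_j,) bool
    gt_rot: np.ndarray | None = None         # (r_i, 3, 3)
    gt_trans: np.ndarray | None = None       # (r_i, 3)
    gt_sincos: np.ndarray | None = None      # (r_i, 7, 2)
    gt_torsion_defined: np.ndarray | None = None
    gt_atoms: np.ndarray | None = None       # (r_i, 14, 3)
    gt_atom_mask: np.ndarray | None = None
    affinity: float | None = None
    binder: bool | None = None

    @property
    def has_label(self) -> bool:
        return self.affinity is not None

    @property
    def has_structure(self) -> bool:
        return self.gt_rot is not None


def bundle_from_complex(
    complex: PMHCComplex,
    kd_nM: float | None = None,
    c_s: int = C_S_DEFAULT,
    cross_cutoff: float = CROSS_MASK_CUTOFF,
    cross_mask: np.ndarray | None = None,
    with_structure: bool = True,
) -> FeatureBundle:
    """Featurize a superposed complex into one record.

    ``cross_mask`` may be supplied directly (precomputed mask files); by
    default it is derived from groove-center proximity.
    """
    mhc_frames = geo.frames_from_atoms(complex.mhc_coords)
    mrot, mtrans = geo.frames_to_arrays(mhc_frames)
    if cross_mask is None:
        cross_mask = build_cross_mask(complex, cutoff=cross_cutoff)
    gt = {}
    if with_structure:
        pep_frames = geo.frames_from_atoms(complex.pep_coords)
        prot, ptrans = geo.frames_to_arrays(pep_frames)
        tors = geo.extract_torsions(complex.pep_coords, complex.pep_seq,
                                    complex.pep_mask)
        gt = dict(
            gt_rot=prot,
            gt_trans=ptrans,
            gt_sincos=tors.sincos(),
            gt_torsion_defined=tors.defined,
            gt_atoms=complex.pep_coords,
            gt_atom_mask=complex.pep_mask,
        )
    return FeatureBundle(
        entry_id=complex.entry_id,
        pep_seq=complex.pep_seq,
        mhc_seq=complex.mhc_seq,
        pep_onehot=one_hot(complex.pep_seq, c_s),
        mhc_onehot=one_hot(complex.mhc_seq, c_s),
        proximity=proximity_matrix(complex),
        mhc_rot=mrot,
        mhc_trans=mtrans,
        cross_mask=np.asarray(cross_mask, dtype=bool),
        affinity=None if kd_nM is None else ba_target(kd_nM),
        binder=None if kd_nM is None else classify_binder(kd_nM),
        **gt,
    )


# ---------------------------------------------------------------------------
# HDF5 dataset store
#
# Layout: one group per record id containing datasets named after the
# FeatureBundle arrays plus string attrs `pep_seq`, `mhc_seq` and, when
# labeled, scalar attrs `affinity` and `binder`.

_ARRAY_FIELDS = (
    "pep_onehot", "mhc_onehot", "proximity", "mhc_rot", "mhc_trans",
    "cross_mask", "gt_rot", "gt_trans", "gt_sincos", "gt_torsion_defined",
    "gt_atoms", "gt_atom_mask",
)


def build_dataset(records, out_path) -> int:
    """Write FeatureBundles to an HDF5 file; returns the record count.
    Duplicate record ids raise."""
    n = 0
    with h5py.File(os.fspath(out_path), "w") as fh:
        for rec in records:
            if rec.entry_id in fh:
                raise ValueError(f"duplicate record id {rec.entry_id!r}")
            g = fh.create_group(rec.entry_id)
            g.attrs["pep_seq"] = rec.pep_seq
            g.attrs["mhc_seq"] = rec.mhc_seq
            for name in _ARRAY_FIELDS:
                arr = getattr(rec, name)
                if arr is not None:
                    g.create_dataset(name, data=np.asarray(arr))
            if rec.has_label:
                g.attrs["affinity"] = float(rec.affinity)
                g.attrs["binder"] = bool(rec.binder)
            n += 1
    return n


class DatasetStore:
    """Random-access reader over a preprocessed HDF5 dataset."""

    def __init__(self, path):
        self._fh = h5py.File(os.fspath(path), "r")
        self.ids = sorted(self._fh.keys())

    def __len__(self) -> int:
        return len(self.ids)

    def __getitem__(self, key) -> FeatureBundle:
        if isinstance(key, (int, np.integer)):
            key = self.ids[key]
        g = self._fh[key]
        kw = {}
        for name in _ARRAY_FIELDS:
            kw[name] = g[name][()] if name in g else None
        kw["cross_mask"] = kw["cross_mask"].astype(bool)
        if kw["gt_torsion_defined"] is not None:
            kw["gt_torsion_defined"] = kw["gt_torsion_defined"].astype(bool)
        if kw["gt_atom_mask"] is not None:
            kw["gt_atom_mask"] = kw["gt_atom_mask"].astype(bool)
        return FeatureBundle(
            entry_id=key,
            pep_seq=str(g.attrs["pep_seq"]),
            mhc_seq=str(g.attrs["mhc_seq"]),
            affinity=float(g.attrs["affinity"]) if "affinity" in g.attrs else None,
            binder=bool(g.attrs["binder"]) if "binder" in g.attrs else None,
            **kw,
        )

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def load_dataset(path) -> DatasetStore:
    return DatasetStore(path)
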