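"""Structure-evaluation protocol: clashes, chirality, Ramachandran, omega
cis/trans labels, and groove-anchored peptide CA-RMSD.

The clash rule lists every non-excepted heavy-atom pair closer than the sum
of their van der Waals radii (Bondi set, shipped in
:mod:`pmhcnet.residues`).  Excepted pairs: hydrogens, atoms within one
residue, backbone-backbone pairs of peptide-bonded residues, the side chain
of a proline against the backbone of a bonded neighbor (the proline side
chain closes onto its own backbone), and the SG-SG pair of two cysteines
that could be disulfide bonded.  Following the evaluation protocol these
analyses are run on the modeled peptide chain.

Omega windows: trans for omega in [160, 200] mod 360 (i.e. |omega| >= 160),
cis for [-20, 20]; anything else is labeled "other".  Both windows are
closed at their boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dataprep as dp
from . import geometry as geo
from . import residues as rc


@dataclass
class Clash:
    res_a: int
    atom_a: str
    res_b: int
    atom_b: str
    distance: float
    overlap: float


@dataclass
class QCReport:
    clashes: list = field(default_factory=list)
    overlap_sum: float = 0.0
    chirality: list = field(default_factory=list)   # 'L' | 'D' | 'achiral'
    phi_psi: np.ndarray | None = None               # (r, 2), nan if undefined
    omegas: list = field(default_factory=list)      # (omega_deg | None, label)
    ca_rmsd: float | None = None


def _radius(atom_name: str, radii) -> float:
    el = rc.element_of(atom_name)
    if el not in radii:
        raise KeyError(f"no van der Waals radius for element {el!r} ({atom_name})")
    return radii[el]


def _peptide_bonded(coords, mask, i, j) -> bool:
    """Adjacent in sequence and actually peptide-bonded (C-N < 2 A)."""
    if abs(i - j) != 1:
        return False
    a, b = (i, j) if i < j else (j, i)
    if not (mask[a, 2] and mask[b, 0]):
        return False
    return np.linalg.norm(coords[b, 0] - coords[a, 2]) < 2.0


def detect_clashes(
    coords: np.ndarray,
    mask: np.ndarray,
    seq: str,
    radii: dict | None = None,
):
    """Van der Waals clashes within one chain.

    Returns ``(clashes, overlap_sum)``; each pair is reported once.
    """
    radii = radii or rc.VDW_RADII
    coords = np.asarray(coords, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    r = len(seq)
    layouts = [rc.get_layout(rc.AA1_TO_AA3[a]) for a in seq]
    clashes = []
    for i in range(r):
        li = layouts[i]
        for jj in range(i + 1, r):
            lj = layouts[jj]
            bonded = _peptide_bonded(coords, mask, i, jj)
            pro_pair = bonded and ("P" in (seq[i], seq[jj]))
            for si, name_i in enumerate(li.atom14_names):
                if not mask[i, si]:
                    continue
                bb_i = name_i in rc.BACKBONE_ATOMS
                for sj, name_j in enumerate(lj.atom14_names):
                    if not mask[jj, sj]:
                        continue
                    bb_j = name_j in rc.BACKBONE_ATOMS
                    if bonded and bb_i and bb_j:
                        continue
                    if pro_pair:
                        # proline side chain against the neighbor's backbone
                        if seq[i] == "P" and not bb_i and bb_j:
                            continue
                        if seq[jj] == "P" and not bb_j and bb_i:
                            continue
                    if (
                        seq[i] == "C" and seq[jj] == "C"
                        and name_i == "SG" and name_j == "SG"
                    ):
                        continue
                    limit = _radius(name_i, radii) + _radius(name_j, radii)
                    d = float(np.linalg.norm(coords[i, si] - coords[jj, sj]))
                    if d < limit:
                        clashes.append(
                            Clash(i, name_i, jj, name_j, d, limit - d)
                        )
    return clashes, float(sum(c.overlap for c in clashes))


def chirality(coords: np.ndarray, mask: np.ndarray, aa1: str) -> str:
    """L / D / achiral call for one residue from the signed volume of
    (N-CA, C-CA, CB-CA)."""
    if aa1 == "G":
        return "achiral"
    lay = rc.get_layout(rc.AA1_TO_AA3[aa1])
    cb = lay.slot("CB")
    if not (mask[0] and mask[1] and mask[2] and mask[cb]):
        raise ValueError(f"chirality of {aa1} needs N, CA, C and CB")
    det = np.linalg.det(
        np.stack([coords[0] - coords[1], coords[2] - coords[1],
                  coords[cb] - coords[1]])
    )
    return "L" if det > 0 else "D"


def chirality_calls(coords: np.ndarray, mask: np.ndarray, seq: str) -> list[str]:
    return [chirality(coords[i], mask[i], a) for i, a in enumerate(seq)]


def ramachandran(coords: np.ndarray, seq: str, mask: np.ndarray | None = None):
    """Per-residue (phi, psi) in degrees; nan where undefined (termini)."""
    tors = geo.extract_torsions(coords, seq, mask)
    out = np.full((len(seq), 2), np.nan)
    # psi here follows the strict inter-residue definition: the C-terminal
    # residue (no following N) is reported undefined, as in Ramachandran
    # practice, even though placement can infer it from the carbonyl O.
    for i in range(len(seq)):
        if tors.defined[i, 0]:
            out[i, 0] = tors.angles_deg[i, 0]
        if tors.defined[i, 1] and i + 1 < len(seq):
            out[i, 1] = tors.angles_deg[i, 1]
    return out


def omega_label(omega_deg: float) -> str:
    w = (omega_deg + 180.0) % 360.0 - 180.0
    if abs(w) >= 160.0:
        return "trans"
    if abs(w) <= 20.0:
        return "cis"
    return "other"


def omega_labels(coords: np.ndarray, seq: str, mask: np.ndarray | None = None):
    """(omega, label) per peptide bond; omega is None for unbonded gaps."""
    tors = geo.extract_torsions(coords, seq, mask)
    out = []
    for i in range(1, len(seq)):
        if tors.defined[i, 2]:
            w = float(tors.angles_deg[i, 2])
            out.append((w, omega_label(w)))
        else:
            out.append((None, "unbonded"))
    return out


def anchored_ca_rmsd(
    model: dp.PMHCComplex,
    reference: dp.PMHCComplex,
    omit_nterm: int = 2,
    omit_cterm: int = 1,
) -> float:
    """Peptide CA-RMSD after superposing on the G-domain.

    The rigid fit uses sequence-aligned G-domain CA pairs, excluding the
    first ``omit_nterm`` and last ``omit_cterm`` reference positions (their
    conformation varies between structures); the fitted transform is applied
    to the whole model and the RMSD is computed over peptide CA atoms only.
    """
    if len(model.pep_seq) != len(reference.pep_seq):
        raise ValueError("peptide length mismatch between model and reference")
    ia, ib, _ = dp.align_gdomains(model.mhc_seq, reference.mhc_seq)
    lo, hi = omit_nterm, len(reference.mhc_seq) - omit_cterm
    keep = (ib >= lo) & (ib < hi)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 G-domain CA pairs available for the fit")
    R, t = dp._kabsch(model.mhc_coords[ia[keep], 1],
                      reference.mhc_coords[ib[keep], 1])
    pep = model.pep_coords[:, 1] @ R.T + t
    return float(np.sqrt(((pep - reference.pep_coords[:, 1]) ** 2).sum(-1).mean()))


def qc_report(
    complex: dp.PMHCComplex, reference: dp.PMHCComplex | None = None
) -> QCReport:
    """Full evaluation of one complex (peptide-chain analyses)."""
    clashes, total = detect_clashes(
        complex.pep_coords, complex.pep_mask, complex.pep_seq
    )
    rep = QCReport(
        clashes=clashes,
        overlap_sum=total,
        chirality=chirality_calls(
            complex.pep_coords, complex.pep_mask, complex.pep_seq
        ),
        phi_psi=ramachandran(complex.pep_coords, complex.pep_seq, complex.pep_mask),
        omegas=omega_labels(complex.pep_coords, complex.pep_seq, complex.pep_mask),
    )
    if reference is not None:
        rep.ca_rmsd = anchored_ca_rmsd(complex, reference)
    return rep
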