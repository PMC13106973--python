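"""Amino-acid constants: atom layout, torsion definitions, rigid groups.

Every residue is carried in a fixed 14-slot heavy-atom layout (``atom14``):
slot 0..3 are always N, CA, C, O; slot 4 is CB where present; the remaining
side-chain atoms follow in chemical-component-dictionary order.  Tryptophan
fills all 14 slots.

The torsion parameterization follows the rigid-group picture: each residue
owns a backbone rigid group (N, CA, C and CB) plus one rigid group per
torsion angle.  The omega group is empty; the phi group contains only the
amide hydrogen (placed on demand, never part of the heavy-atom arrays); the
psi group contains the carbonyl O; the chi1..chi4 groups contain the
side-chain atoms distal to each rotatable bond.

Ideal internal coordinates are derived once, at first use, from the ideal
residue geometries bundled with biotite (the PDB chemical component
dictionary) rather than from a hand-typed table; the derivation below is the
single source of truth for the canonical backbone triangle and all
group-local coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

# Residue-type order used for one-hot indices (alphabetical by full name).
AA1_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA3_ORDER = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]
AA1_TO_AA3 = dict(zip(AA1_ORDER, AA3_ORDER))
AA3_TO_AA1 = {v: k for k, v in AA1_TO_AA3.items()}
AA1_TO_INDEX = {a: i for i, a in enumerate(AA1_ORDER)}
AA3_TO_INDEX = {a: i for i, a in enumerate(AA3_ORDER)}

N_ATOM_SLOTS = 14
BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Torsion channel order used throughout the package.
TORSION_NAMES = ("phi", "psi", "omega", "chi1", "chi2", "chi3", "chi4")
N_TORSIONS = 7

# Rigid-group order: backbone, phi, psi, omega, chi1..chi4.
GROUP_NAMES = ("backbone", "phi", "psi", "omega", "chi1", "chi2", "chi3", "chi4")
N_GROUPS = 8

# chi angle atom quadruples (standard side-chain torsion definitions).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ALA": [],
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "CYS": [("N", "CA", "CB", "SG")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLY": [],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PRO": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "SER": [("N", "CA", "CB", "OG")],
    "THR": [("N", "CA", "CB", "OG1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "VAL": [("N", "CA", "CB", "CG1")],
}

# Ideal peptide-bond geometry for chaining residues (Engh & Huber values).
PEPTIDE_BOND_LENGTH = 1.329      # C(i)-N(i+1), Angstrom
ANGLE_CA_C_N = 116.2             # CA(i)-C(i)-N(i+1), degrees
ANGLE_C_N_CA = 121.7             # C(i)-N(i+1)-CA(i+1), degrees

# van der Waals radii (Bondi set), by element, Angstrom.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80}

# Ideal C(alpha)-H(alpha) bond length, Angstrom.
CA_HA_BOND_LENGTH = 1.09


def dihedral(p1, p2, p3, p4):
    """Signed dihedral angle p1-p2-p3-p4 in degrees, range (-180, 180].

    Vectorized over leading dimensions.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2n, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 exactly to +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def _gram_schmidt_rotation(v_x: np.ndarray, v_plane: np.ndarray) -> np.ndarray:
    """Rotation whose x-axis is along v_x and whose xy-plane contains v_plane
    (v_plane on the +y side).  Columns of the returned matrix are the axes."""
    e1 = v_x / np.linalg.norm(v_x)
    u = v_plane - np.dot(v_plane, e1) * e1
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        raise ValueError("degenerate geometry: collinear reference points")
    e2 = u / nu
    e3 = np.cross(e1, e2)
    return np.stack([e1, e2, e3], axis=-1)


def _frame_from_three(origin, x_point, plane_point):
    """4x4 homogeneous frame: origin at `origin`, x-axis toward `x_point`,
    `plane_point` in the +y half of the xy-plane."""
    R = _gram_schmidt_rotation(np.asarray(x_point) - origin,
                               np.asarray(plane_point) - origin)
    M = np.eye(4)
    M[:3, :3] = R
    M[:3, 3] = origin
    return M


def _torsion_frame(a, b, c):
    """Frame of the rigid group rotated by torsion (a, b, c, d): origin at c,
    x-axis along the b->c rotation bond, a defining the zero-dihedral
    direction (+y at dihedral 0)."""
    a, b, c = (np.asarray(p, dtype=np.float64) for p in (a, b, c))
    return _frame_from_three(c, 2 * c - b, c + (a - b))


def _rot_x(theta_deg: float) -> np.ndarray:
    th = np.radians(theta_deg)
    ct, st = np.cos(th), np.sin(th)
    M = np.eye(4)
    M[1, 1] = ct
    M[1, 2] = -st
    M[2, 1] = st
    M[2, 2] = ct
    return M


def _inv(M: np.ndarray) -> np.ndarray:
    out = np.eye(4)
    R = M[:3, :3]
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ M[:3, 3]
    return out


@dataclass(frozen=True)
class ResidueLayout:
    """Derived per-residue-type constants (see module docstring)."""

    name: str                      # three-letter code
    atom14_names: tuple            # heavy atom names, <= 14
    group_index: np.ndarray        # (14,) rigid group per slot (-1 = unused)
    group_local: np.ndarray        # (14, 3) coords in the owning group frame
    group_transforms: np.ndarray   # (8, 4, 4) default transform per group
    group_parent: np.ndarray       # (8,) parent group index (-1 for backbone)
    chi_atoms: tuple               # chi torsion quadruples
    ideal_atom14: np.ndarray       # (14, 3) ideal coords in backbone frame
    atom14_exists: np.ndarray      # (14,) bool

    def slot(self, atom_name: str) -> int:
        return self.atom14_names.index(atom_name)


def _moved_by_chi(names, bonds, chi):
    """Atoms distal to the chi rotation bond (graph search from the bond's
    far atom, never crossing back over the bond nor through the backbone)."""
    b, c = chi[1], chi[2]
    adj = {n: set() for n in names}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    blocked = set(BACKBONE_ATOMS) | {b}
    seen, stack = set(), [c]
    while stack:
        n = stack.pop()
        if n in seen:
            continue
        seen.add(n)
        for m in adj[n]:
            if m not in seen and m not in blocked:
                stack.append(m)
    seen.discard(c)
    return seen


@lru_cache(maxsize=None)
def get_layout(aa3: str) -> ResidueLayout:
    """Build (and cache) the rigid-group layout for one residue type."""
    import biotite.structure.info as _info

    if aa3 not in AA3_TO_INDEX:
        raise KeyError(f"unknown residue type: {aa3!r}")
    res = _info.residue(aa3)
    heavy = res[(res.element != "H")]
    keep = [i for i, n in enumerate(heavy.atom_name) if n != "OXT"]
    names = [str(heavy.atom_name[i]) for i in keep]
    coords = {n: heavy.coord[i].astype(np.float64) for i, n in zip(keep, names)}

    # atom14 ordering: N CA C O CB, then CCD order for the rest
    front = [n for n in ("N", "CA", "C", "O", "CB") if n in names]
    rest = [n for n in names if n not in front]
    atom14 = tuple(front + rest)
    assert len(atom14) <= N_ATOM_SLOTS

    # heavy-atom bond graph (by name)
    bonds = []
    for i, j, _ in res.bonds.as_array():
        ni, nj = str(res.atom_name[i]), str(res.atom_name[j])
        if ni in coords and nj in coords:
            bonds.append((ni, nj))

    chis = CHI_ATOMS[aa3]
    # group of each atom: index of the LAST chi that moves it
    group_of = {}
    for n in names:
        group_of[n] = 0
    if "O" in group_of:
        group_of["O"] = 2  # psi group
    for k, chi in enumerate(chis):
        for n in _moved_by_chi(names, bonds, chi):
            group_of[n] = 4 + k
        group_of[chi[3]] = max(group_of.get(chi[3], 0), 4 + k)

    # frames at ideal geometry
    bb_frame = _frame_from_three(coords["CA"], coords["C"], coords["N"])
    frames = {0: bb_frame}
    parents = np.full(N_GROUPS, -1, dtype=np.int64)
    transforms = np.tile(np.eye(4), (N_GROUPS, 1, 1))

    # psi group: torsion atoms (N, CA, C, O); the placement angle is the
    # standard psi, related to dihedral(N,CA,C,O) by +180 deg (sp2 carbonyl).
    psi0 = float(dihedral(coords["N"], coords["CA"], coords["C"], coords["O"])) + 180.0
    f_psi = _torsion_frame(coords["N"], coords["CA"], coords["C"])
    frames[2] = f_psi
    parents[2] = 0
    transforms[2] = _inv(bb_frame) @ f_psi @ _rot_x(-psi0)

    # chi groups chain off the backbone: each group's default transform is
    # expressed relative to its parent's ideal frame, with the ideal torsion
    # factored out so that G_k(theta) = G_{k-1} T_k Rx(theta) reproduces the
    # ideal coordinates at theta = theta0.
    prev_group = 0
    for k, chi in enumerate(chis):
        g = 4 + k
        a, b, c, d = chi
        th0 = float(dihedral(coords[a], coords[b], coords[c], coords[d]))
        f_g = _torsion_frame(coords[a], coords[b], coords[c])
        parents[g] = prev_group
        transforms[g] = _inv(frames[prev_group]) @ f_g @ _rot_x(-th0)
        frames[g] = f_g
        prev_group = g

    group_index = np.full(N_ATOM_SLOTS, -1, dtype=np.int64)
    group_local = np.zeros((N_ATOM_SLOTS, 3))
    ideal_atom14 = np.zeros((N_ATOM_SLOTS, 3))
    exists = np.zeros(N_ATOM_SLOTS, dtype=bool)
    inv_frames = {g: _inv(f) for g, f in frames.items()}
    for s, n in enumerate(atom14):
        g = group_of[n]
        group_index[s] = g
        p = np.append(coords[n], 1.0)
        group_local[s] = (inv_frames[g] @ p)[:3]
        ideal_atom14[s] = (_inv(bb_frame) @ p)[:3]
        exists[s] = True

    return ResidueLayout(
        name=aa3,
        atom14_names=atom14,
        group_index=group_index,
        group_local=group_local,
        group_transforms=transforms,
        group_parent=parents,
        chi_atoms=tuple(chis),
        ideal_atom14=ideal_atom14,
        atom14_exists=exists,
    )


@lru_cache(maxsize=1)
def stacked_layouts():
    """All 20 layouts stacked into arrays indexed by residue-type index.

    Returns a dict with keys:
      group_index   (20, 14) int
      group_local   (20, 14, 3)
      transforms    (20, 8, 4, 4)
      exists        (20, 14) bool
      ideal_atom14  (20, 14, 3)
      chi_defined   (20, 4) bool
    """
    gi = np.stack([get_layout(a).group_index for a in AA3_ORDER])
    gl = np.stack([get_layout(a).group_local for a in AA3_ORDER])
    tr = np.stack([get_layout(a).group_transforms for a in AA3_ORDER])
    ex = np.stack([get_layout(a).atom14_exists for a in AA3_ORDER])
    ia = np.stack([get_layout(a).ideal_atom14 for a in AA3_ORDER])
    cd = np.zeros((20, 4), dtype=bool)
    for i, a in enumerate(AA3_ORDER):
        cd[i, : len(CHI_ATOMS[a])] = True
    return {
        "group_index": gi,
        "group_local": gl,
        "transforms": tr,
        "exists": ex,
        "ideal_atom14": ia,
        "chi_defined": cd,
    }


def group_members(aa3: str) -> dict[str, list[str]]:
    """Atom names per rigid group, including the on-demand amide hydrogen.

    The omega group is empty.  The phi group carries exactly one atom — the
    amide H, which exists only when hydrogens are requested (and not at all
    for proline, whose ring nitrogen has no amide H).  The psi group carries
    the carbonyl O.  Heavy-atom arrays never include the phi group's H.
    """
    lay = get_layout(aa3)
    out: dict[str, list[str]] = {name: [] for name in GROUP_NAMES}
    for s, atom in enumerate(lay.atom14_names):
        out[GROUP_NAMES[lay.group_index[s]]].append(atom)
    if aa3 != "PRO":
        out["phi"].append("H")
    return out


def seq_to_indices(seq: str) -> np.ndarray:
    """Residue-type indices for a one-letter sequence.  Raises on letters
    outside the 20 standard amino acids."""
    try:
        return np.array([AA1_TO_INDEX[c] for c in seq], dtype=np.int64)
    except KeyError as e:
        raise ValueError(f"non-standard amino-acid letter: {e.args[0]!r}") from None


def element_of(atom_name: str) -> str:
    """Element of a heavy protein atom from its PDB name."""
    return atom_name[0]
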