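"""Rigid-frame and torsion-angle machinery.

A residue backbone is modeled as a rigid triangle (N, CA, C) carried by a
local *frame*: a unit quaternion plus a translation mapping the canonical
triangle (CA at the origin, C on +x, N in the xy-plane) into the global
coordinate system.  Side chains are generated from the frame through the
rigid-group torsion parameterization in :mod:`pmhcnet.residues`.

Atom placement has two entry points: :func:`place_atoms` (plain arrays) and
:func:`atoms_from_frames_torsions_t`, the differentiable core used by the
structure losses; the former is a thin wrapper over the latter so there is a
single placement implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from . import residues as rc
from .residues import dihedral

_QUAT_TOL = 1e-6


# ---------------------------------------------------------------------------
# quaternions


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of a unit quaternion (w, x, y, z)."""
    q = np.asarray(q, dtype=np.float64)
    n = np.linalg.norm(q)
    if abs(n - 1.0) > _QUAT_TOL:
        raise ValueError(f"quaternion norm {n:.8f} deviates from 1 beyond tolerance")
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def matrix_to_quat(R: np.ndarray) -> np.ndarray:
    """Unit quaternion (w >= 0 convention) of a rotation matrix."""
    R = np.asarray(R, dtype=np.float64)
    t = np.trace(R)
    if t > 0:
        s = np.sqrt(t + 1.0) * 2
        q = np.array(
            [0.25 * s, (R[2, 1] - R[1, 2]) / s, (R[0, 2] - R[2, 0]) / s,
             (R[1, 0] - R[0, 1]) / s]
        )
    else:
        i = int(np.argmax(np.diag(R)))
        j, k = (i + 1) % 3, (i + 2) % 3
        s = np.sqrt(1.0 + R[i, i] - R[j, j] - R[k, k]) * 2
        q = np.empty(4)
        q[0] = (R[k, j] - R[j, k]) / s
        q[1 + i] = 0.25 * s
        q[1 + j] = (R[j, i] + R[i, j]) / s
        q[1 + k] = (R[k, i] + R[i, k]) / s
    q /= np.linalg.norm(q)
    if q[0] < 0:
        q = -q
    return q


def quat_multiply(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = q1
    w2, x2, y2, z2 = q2
    return np.array(
        [
            w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
            w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
            w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
            w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
        ]
    )


# ---------------------------------------------------------------------------
# frames


@dataclass
class Frame:
    """Rigid transform: unit quaternion rotation + translation (Angstrom)."""

    quaternion: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        q = np.asarray(self.quaternion, dtype=np.float64)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-3:
            raise ValueError(f"quaternion norm {n:.6f} is not 1")
        q = q / n
        if q[0] < 0:
            q = -q
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64)
        )

    @classmethod
    def identity(cls) -> "Frame":
        return cls()

    @classmethod
    def from_rotation_matrix(cls, R: np.ndarray, t=np.zeros(3)) -> "Frame":
        return cls(matrix_to_quat(R), t)

    @classmethod
    def from_matrix4(cls, M: np.ndarray) -> "Frame":
        return cls(matrix_to_quat(M[:3, :3]), M[:3, 3])

    @property
    def rotation_matrix(self) -> np.ndarray:
        return quat_to_matrix(self.quaternion)

    def to_matrix4(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation_matrix
        M[:3, 3] = self.translation
        return M

    def compose(self, other: "Frame") -> "Frame":
        q = quat_multiply(self.quaternion, other.quaternion)
        q /= np.linalg.norm(q)
        t = self.rotation_matrix @ other.translation + self.translation
        return Frame(q, t)

    def inverse(self) -> "Frame":
        qi = self.quaternion * np.array([1.0, -1, -1, -1])
        return Frame(qi, -(quat_to_matrix(qi) @ self.translation))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation_matrix.T + self.translation

    def apply_inverse(self, points: np.ndarray) -> np.ndarray:
        return (np.asarray(points) - self.translation) @ self.rotation_matrix


def compose_frames(a: Frame, b: Frame) -> Frame:
    """a then b in a's coordinates (equals the 4x4 homogeneous product)."""
    return a.compose(b)


def frame_from_backbone(n, ca, c) -> Frame:
    """Backbone frame from N, CA, C positions (Gram-Schmidt on (C-CA, N-CA)).

    Raises ``ValueError`` for collinear input points.
    """
    n, ca, c = (np.asarray(p, dtype=np.float64) for p in (n, ca, c))
    R = rc._gram_schmidt_rotation(c - ca, n - ca)
    return Frame(matrix_to_quat(R), ca)


def frames_from_atoms(coords: np.ndarray) -> list[Frame]:
    """One backbone frame per residue from atom14 coordinates (slots N/CA/C)."""
    return [frame_from_backbone(r[0], r[1], r[2]) for r in np.asarray(coords)]


def frames_to_arrays(frames) -> tuple[np.ndarray, np.ndarray]:
    """Stack frames into (r, 3, 3) rotations and (r, 3) translations."""
    rot = np.stack([f.rotation_matrix for f in frames])
    trans = np.stack([f.translation for f in frames])
    return rot, trans


# ---------------------------------------------------------------------------
# torsions


@dataclass
class TorsionSet:
    """Per-residue torsion angles in degrees, range (-180, 180].

    ``angles_deg`` is (r, 7) ordered phi, psi, omega, chi1..chi4;
    ``defined`` flags angles that exist (chain termini and residue types
    without a given chi are flagged, never silently zero).
    """

    angles_deg: np.ndarray
    defined: np.ndarray

    def __post_init__(self):
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        self.defined = np.asarray(self.defined, dtype=bool)
        if self.angles_deg.shape != self.defined.shape or self.angles_deg.shape[-1] != rc.N_TORSIONS:
            raise ValueError("TorsionSet arrays must both be (r, 7)")

    @property
    def n_residues(self) -> int:
        return self.angles_deg.shape[0]

    def sincos(self) -> np.ndarray:
        """(r, 7, 2) sin/cos pairs; undefined angles map to (0, 1)."""
        rad = np.radians(self.angles_deg)
        sc = np.stack([np.sin(rad), np.cos(rad)], axis=-1)
        sc[~self.defined] = (0.0, 1.0)
        return sc

    @classmethod
    def from_sincos(cls, sincos: np.ndarray, defined: np.ndarray) -> "TorsionSet":
        ang = np.degrees(np.arctan2(sincos[..., 0], sincos[..., 1]))
        ang = np.where(np.isclose(ang, -180.0), 180.0, ang)
        return cls(ang, defined)


def _required_defined(torsions: TorsionSet, aatype: np.ndarray) -> None:
    consts = rc.stacked_layouts()
    chi_req = consts["chi_defined"][aatype]          # (r, 4)
    need = np.zeros((len(aatype), rc.N_TORSIONS), dtype=bool)
    need[:, 1] = True                                 # psi places the carbonyl O
    need[:, 3:] = chi_req
    missing = need & ~torsions.defined
    if missing.any():
        i, j = np.argwhere(missing)[0]
        raise ValueError(
            f"undefined required torsion {rc.TORSION_NAMES[j]!r} "
            f"for residue {i} ({rc.AA3_ORDER[aatype[i]]})"
        )


def _rx_from_sincos_t(sincos: ag.Tensor) -> ag.Tensor:
    """(..., 2) sin/cos -> (..., 3, 3) rotation about the x-axis."""
    s = sincos[..., 0]
    c = sincos[..., 1]
    one = ag.Tensor(np.ones_like(s.data))
    zero = ag.Tensor(np.zeros_like(s.data))
    rows = [
        ag.stack([one, zero, zero], axis=-1),
        ag.stack([zero, c, -s], axis=-1),
        ag.stack([zero, s, c], axis=-1),
    ]
    return ag.stack(rows, axis=-2)


def atoms_from_frames_torsions_t(
    rot: ag.Tensor, trans: ag.Tensor, sincos: ag.Tensor, aatype: np.ndarray
) -> ag.Tensor:
    """Differentiable all-atom placement.

    Parameters are backbone rotations (r, 3, 3), translations (r, 3),
    torsion sin/cos (r, 7, 2) and residue-type indices (r,).  Returns atom14
    coordinates (r, 14, 3); slots that do not exist for a residue type are
    produced but carry no meaning (mask them with the layout table).
    """
    consts = rc.stacked_layouts()
    r = len(aatype)
    T = consts["transforms"][aatype]                 # (r, 8, 4, 4) constants
    group_index = np.maximum(consts["group_index"][aatype], 0)  # (r, 14)
    local = consts["group_local"][aatype]            # (r, 14, 3)

    rot = ag.astensor(rot)
    trans = ag.astensor(trans)
    sincos = ag.astensor(sincos)

    # group chain: backbone -> psi; backbone -> chi1 -> ... -> chi4
    # torsion channel per group: psi=1, chi_k=3+k
    g_rot = {0: rot}
    g_tr = {0: trans}
    parent_of = {2: 0, 4: 0, 5: 4, 6: 5, 7: 6}
    channel_of = {2: 1, 4: 3, 5: 4, 6: 5, 7: 6}
    for g in (2, 4, 5, 6, 7):
        p = parent_of[g]
        T_R = ag.Tensor(np.ascontiguousarray(T[:, g, :3, :3]))
        T_t = ag.Tensor(np.ascontiguousarray(T[:, g, :3, 3]))
        rx = _rx_from_sincos_t(sincos[:, channel_of[g], :])      # (r, 3, 3)
        g_rot[g] = g_rot[p] @ T_R @ rx
        g_tr[g] = (g_rot[p] @ T_t.reshape(r, 3, 1)).reshape(r, 3) + g_tr[p]

    # stack frames for groups 0..7 (phi/omega reuse the backbone frame: they
    # own no heavy atoms) and gather per atom slot
    all_rot = ag.stack(
        [g_rot.get(g, g_rot[0]) for g in range(rc.N_GROUPS)], axis=1
    )  # (r, 8, 3, 3)
    all_tr = ag.stack([g_tr.get(g, g_tr[0]) for g in range(rc.N_GROUPS)], axis=1)

    ridx = np.arange(r)[:, None]
    R_slot = all_rot[ridx, group_index]              # (r, 14, 3, 3)
    t_slot = all_tr[ridx, group_index]               # (r, 14, 3)
    pos = (R_slot @ ag.Tensor(local[..., None])).reshape(r, 14, 3) + t_slot
    return pos


def place_atoms(frames, torsions: TorsionSet, sequence) -> tuple[np.ndarray, np.ndarray]:
    """All-atom coordinates from backbone frames and torsion angles.

    ``frames`` is a sequence of :class:`Frame` (one per residue), ``sequence``
    a one-letter string (or list of one-letter codes).  Returns
    ``(coords, exists)`` with shapes (r, 14, 3) and (r, 14); non-existing
    slots are zeroed.  Raises if a required torsion is undefined.
    """
    aatype = rc.seq_to_indices("".join(sequence))
    if len(frames) != len(aatype) or torsions.n_residues != len(aatype):
        raise ValueError("frames, torsions and sequence lengths disagree")
    _required_defined(torsions, aatype)
    rot, trans = frames_to_arrays(frames)
    out = atoms_from_frames_torsions_t(
        ag.Tensor(rot), ag.Tensor(trans), ag.Tensor(torsions.sincos()), aatype
    ).data
    exists = rc.stacked_layouts()["exists"][aatype]
    return np.where(exists[..., None], out, 0.0), exists


def extract_torsions(
    coords: np.ndarray, sequence, atom_mask: np.ndarray | None = None
) -> TorsionSet:
    """Torsion angles of an atom14 structure.

    phi/psi/omega follow the standard inter-residue definitions; the psi of
    the final residue (no following N) is inferred from the carbonyl O via
    the sp2-planarity relation psi = dihedral(N, CA, C, O) + 180.  Chain
    breaks (peptide C-N distance > 2.0 A) make the spanning angles
    undefined.  Missing defining atoms flag the angle undefined rather than
    raising.
    """
    coords = np.asarray(coords, dtype=np.float64)
    aatype = rc.seq_to_indices("".join(sequence))
    r = len(aatype)
    consts = rc.stacked_layouts()
    if atom_mask is None:
        atom_mask = consts["exists"][aatype]
    angles = np.zeros((r, rc.N_TORSIONS))
    defined = np.zeros((r, rc.N_TORSIONS), dtype=bool)

    N, CA, C, O = coords[:, 0], coords[:, 1], coords[:, 2], coords[:, 3]
    has = atom_mask[:, :4].all(axis=1)
    bonded = np.zeros(r, dtype=bool)
    if r > 1:
        d = np.linalg.norm(N[1:] - C[:-1], axis=-1)
        bonded[1:] = (d < 2.0) & has[1:] & has[:-1]

    for i in range(r):
        if bonded[i]:  # phi(i), omega(i) need the previous residue
            angles[i, 0] = dihedral(C[i - 1], N[i], CA[i], C[i])
            defined[i, 0] = True
            angles[i, 2] = dihedral(CA[i - 1], C[i - 1], N[i], CA[i])
            defined[i, 2] = True
        if i + 1 < r and bonded[i + 1]:
            angles[i, 1] = dihedral(N[i], CA[i], C[i], N[i + 1])
            defined[i, 1] = True
        elif atom_mask[i, :4].all():
            psi = dihedral(N[i], CA[i], C[i], O[i]) + 180.0
            angles[i, 1] = psi - 360.0 if psi > 180.0 else psi
            defined[i, 1] = True
        lay = rc.get_layout(rc.AA3_ORDER[aatype[i]])
        for k, chi in enumerate(lay.chi_atoms):
            slots = [lay.slot(a) for a in chi]
            if all(atom_mask[i, s] for s in slots):
                angles[i, 3 + k] = dihedral(*(coords[i, s] for s in slots))
                defined[i, 3 + k] = True
    return TorsionSet(angles, defined)


def place_chiral_hydrogen(coords: np.ndarray, aa1: str) -> np.ndarray | None:
    """Position of the alpha hydrogen on the chiral CA.

    The HA is placed along the negative vector sum of the CA->N, CA->C and
    CA->CB unit vectors (ideal tetrahedral direction), which preserves the
    handedness of the input residue.  Glycine is achiral: returns ``None``
    and the structure is left untouched.
    """
    if aa1 == "G":
        return None
    lay = rc.get_layout(rc.AA1_TO_AA3[aa1])
    coords = np.asarray(coords, dtype=np.float64)
    ca = coords[1]
    u = np.zeros(3)
    for slot in (0, 2, lay.slot("CB")):
        v = coords[slot] - ca
        u += v / np.linalg.norm(v)
    u = -u / np.linalg.norm(u)
    return ca + rc.CA_HA_BOND_LENGTH * u


# ---------------------------------------------------------------------------
# torsion-driven backbone chains (used by the synthetic fixtures)


def _nerf(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place the next atom from three predecessors and internal coordinates."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(tor),
            bond * np.sin(ang) * np.sin(tor),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def backbone_frames_from_torsions(
    sequence: str,
    phi: np.ndarray,
    psi: np.ndarray,
    omega: np.ndarray,
    start: Frame | None = None,
) -> list[Frame]:
    """Backbone frames of a chain built from phi/psi/omega.

    The first residue sits at ``start`` (identity frame by default); each
    following residue is chained with ideal peptide-bond geometry, so that
    :func:`extract_torsions` on the placed atoms returns the requested
    angles.  ``phi[0]`` and ``omega[0]`` are ignored.
    """
    aatype = rc.seq_to_indices(sequence)
    consts = rc.stacked_layouts()
    ideal = consts["ideal_atom14"]
    start = start or Frame.identity()
    frames = [start]
    n, ca, c = (start.apply(ideal[aatype[0]][s]) for s in range(3))
    for i in range(1, len(aatype)):
        loc = ideal[aatype[i]]
        bond_n_ca = np.linalg.norm(loc[0])
        bond_ca_c = np.linalg.norm(loc[2])
        v1, v2 = loc[0], loc[2]
        ang_n_ca_c = np.degrees(
            np.arccos(v1 @ v2 / (bond_n_ca * bond_ca_c))
        )
        n2 = _nerf(n, ca, c, rc.PEPTIDE_BOND_LENGTH, rc.ANGLE_CA_C_N, psi[i - 1])
        ca2 = _nerf(ca, c, n2, bond_n_ca, rc.ANGLE_C_N_CA, omega[i])
        c2 = _nerf(c, n2, ca2, bond_ca_c, ang_n_ca_c, phi[i])
        frames.append(frame_from_backbone(n2, ca2, c2))
        n, ca, c = n2, ca2, c2
    return frames
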