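"""Geometric substrate: sequences, 3-bead coordinates, rigid frames,
nucleotide templates, ideal A-form construction, and mirror transforms.

The coarse-grained representation of an RNA chain used throughout this
package is a 3-bead model: the phosphate P, the ribose C4', and the
glycosidic nitrogen of the base (N9 for purines, N1 for pyrimidines).
Each residue additionally carries a rigid frame -- a proper rotation plus
a translation -- that maps a predefined local 3-atom template into global
space.  Frames are constructed from bead triads by least-squares (Kabsch)
superposition, i.e. SVD orthogonalization with determinant correction.

The ideal A-form helix is generated from idealized mononucleotide
geometry (heavy atoms from the chemical component dictionary bundled with
biotite) placed under helical symmetry with a 32.7 degree twist and a
2.548 A rise per step; the rigid placement of the nucleotide within the
helix frame is solved once, numerically, for backbone continuity
(O3'(i)-P(i+1) ~ 1.6 A on both strands) and Watson-Crick pairing
geometry, and cached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

# ---------------------------------------------------------------------------
# constants

#: fixed order of the coarse-grained atoms everywhere in the package
BEAD_ATOMS = ("P", "C4'", "N")

ALPHABET = "AUGCN"
PURINES = frozenset("AG")

#: glycosidic nitrogen: N9 for purines, N1 for pyrimidines ('N' aliases 'U')
GLYCOSIDIC_N = {"A": "N9", "G": "N9", "U": "N1", "C": "N1", "N": "N1"}

#: Watson-Crick conjugate bases
WC_CONJUGATE = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: A-form helical parameters: per-step twist (degrees) and rise (Angstrom)
HELIX_TWIST_DEG = 32.7
HELIX_RISE = 2.548

_DET_TOL = 1e-6


class DegenerateGeometryError(ValueError):
    """Raised when a frame is requested for collinear or coincident atoms."""


# ---------------------------------------------------------------------------
# sequences


class NucleotideSequence:
    """An RNA sequence over the 5-letter alphabet A/U/G/C/N."""

    def __init__(self, residues):
        if isinstance(residues, str):
            residues = list(residues)
        residues = [str(r).upper() for r in residues]
        if len(residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        bad = [r for r in residues if r not in ALPHABET]
        if bad:
            raise ValueError(f"invalid nucleotide symbol(s): {sorted(set(bad))}")
        self.residues = residues

    def __len__(self):
        return len(self.residues)

    def __getitem__(self, i):
        return self.residues[i]

    def __iter__(self):
        return iter(self.residues)

    def __str__(self):
        return "".join(self.residues)

    def __eq__(self, other):
        return str(self) == str(other)

    def one_hot(self) -> np.ndarray:
        """L x 5 one-hot encoding in the fixed order A, U, G, C, N."""
        out = np.zeros((len(self), 5))
        for i, r in enumerate(self.residues):
            out[i, ALPHABET.index(r)] = 1.0
        return out


# ---------------------------------------------------------------------------
# rigid frames


@dataclass
class RigidFrame:
    """A proper rotation + translation (an element of SE(3))."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("frame needs a 3x3 rotation and a 3-vector")
        err = np.abs(self.rotation @ self.rotation.T - np.eye(3)).max()
        if err > 1e-5 or abs(np.linalg.det(self.rotation) - 1.0) > _DET_TOL * 10:
            raise ValueError("rotation must be orthogonal with determinant +1")

    @staticmethod
    def identity() -> "RigidFrame":
        return RigidFrame(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.rotation.T + self.translation

    def compose(self, other: "RigidFrame") -> "RigidFrame":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidFrame(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def invert(self) -> "RigidFrame":
        return RigidFrame(self.rotation.T, -self.rotation.T @ self.translation)

    def __eq__(self, other):
        return np.allclose(self.rotation, other.rotation, atol=1e-10) and np.allclose(
            self.translation, other.translation, atol=1e-10
        )


@dataclass
class FrameSet:
    """Per-residue rigid frames for an RNA chain."""

    rotations: np.ndarray  # L x 3 x 3
    translations: np.ndarray  # L x 3

    def __post_init__(self):
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.translations = np.asarray(self.translations, dtype=float)
        if self.rotations.ndim != 3 or self.rotations.shape[1:] != (3, 3):
            raise ValueError("rotations must be L x 3 x 3")
        if self.translations.shape != (len(self), 3):
            raise ValueError("translations must be L x 3")
        dets = np.linalg.det(self.rotations)
        if np.abs(dets - 1.0).max() > _DET_TOL * 10:
            raise ValueError("all rotations must have determinant +1")

    def __len__(self):
        return self.rotations.shape[0]

    def __getitem__(self, i) -> RigidFrame:
        return RigidFrame(self.rotations[i], self.translations[i])

    @staticmethod
    def from_frames(frames) -> "FrameSet":
        return FrameSet(
            np.stack([f.rotation for f in frames]),
            np.stack([f.translation for f in frames]),
        )

    def transformed_by(self, g: RigidFrame) -> "FrameSet":
        """Compose a global rigid motion on the left of every frame."""
        return FrameSet(
            np.einsum("ij,ljk->lik", g.rotation, self.rotations),
            self.translations @ g.rotation.T + g.translation,
        )

    def to_beads(self, sequence, templates=None) -> "BeadStructure":
        """Realize bead coordinates by applying each frame to its residue's
        local 3-atom template."""
        if templates is None:
            templates = derive_templates()
        coords = np.empty((len(self), 3, 3))
        for i, base in enumerate(sequence):
            local = templates[base].local_coords
            coords[i] = local @ self.rotations[i].T + self.translations[i]
        return BeadStructure(coords)


# ---------------------------------------------------------------------------
# bead structures


@dataclass
class BeadStructure:
    """Per-residue coordinates of the three coarse-grained atoms.

    ``coords[i]`` holds the (P, C4', N) positions of residue i, in that
    fixed atom order, in Angstrom.
    """

    coords: np.ndarray  # L x 3 x 3
    mask: np.ndarray = None  # L bool

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (3, 3):
            raise ValueError("coords must be L x 3 x 3")
        if self.mask is None:
            self.mask = np.ones(len(self), dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
        if not np.all(np.isfinite(self.coords[self.mask])):
            raise ValueError("observed residues must have finite coordinates")

    def __len__(self):
        return self.coords.shape[0]

    def atom(self, name: str) -> np.ndarray:
        """L x 3 coordinates of one bead atom ('P', \"C4'\" or 'N')."""
        return self.coords[:, BEAD_ATOMS.index(name), :]


def mirror_structure(s: BeadStructure) -> BeadStructure:
    """Reflect through the z=0 plane.  Distances are preserved, every
    dihedral angle is negated; the result is the enantiomer."""
    coords = s.coords.copy()
    coords[:, :, 2] *= -1.0
    return BeadStructure(coords, s.mask.copy())


# ---------------------------------------------------------------------------
# superposition and frame construction


def kabsch(source: np.ndarray, target: np.ndarray):
    """Least-squares rigid superposition of ``source`` onto ``target``.

    Returns ``(R, t, rmsd)`` minimizing ||R @ source_i + t - target_i||
    with det(R) = +1 (SVD with sign correction).
    """
    P = np.asarray(source, dtype=float)
    Q = np.asarray(target, dtype=float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    resid = P @ R.T + t - Q
    rmsd = float(np.sqrt((resid**2).sum() / len(P)))
    return R, t, rmsd


def proper_orthogonalize(M: np.ndarray) -> np.ndarray:
    """Closest rotation matrix to ``M`` in Frobenius norm (symmetric /
    SVD orthogonalization with determinant correction)."""
    U, _, Vt = np.linalg.svd(np.asarray(M, dtype=float))
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


@dataclass
class NucleotideTemplate:
    """The predefined local 3-atom conformation of one base type."""

    base_type: str
    local_coords: np.ndarray  # 3 x 3, centroid at the origin

    def __post_init__(self):
        self.local_coords = np.asarray(self.local_coords, dtype=float)
        if np.abs(self.local_coords.mean(axis=0)).max() > 1e-9:
            raise ValueError("template centroid must be at the origin")


def _check_noncollinear(points: np.ndarray) -> None:
    p = np.asarray(points, dtype=float)
    a, b, c = p
    area2 = np.linalg.norm(np.cross(b - a, c - a))
    if area2 < 1e-8 or min(
        np.linalg.norm(b - a), np.linalg.norm(c - a), np.linalg.norm(c - b)
    ) < 1e-8:
        raise DegenerateGeometryError(
            "bead triad is collinear or has coincident atoms"
        )


def frame_from_beads(observed: np.ndarray, template: NucleotideTemplate):
    """Construct a rigid frame by Kabsch/SVD superposition of the local
    template onto the observed bead triad.

    Returns ``(RigidFrame, residual_rmsd)``.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.shape != (3, 3):
        raise ValueError("observed must be a 3x3 coordinate array")
    _check_noncollinear(observed)
    R, t, rmsd = kabsch(template.local_coords, observed)
    return RigidFrame(R, t), rmsd


def gram_schmidt_frame(observed: np.ndarray) -> RigidFrame:
    """Gram-Schmidt frame construction (comparator only; the package uses
    SVD orthogonalization).  Axes built from (P, C4', N) as in the
    three-point construction: origin at C4', x along C4'->N, y in the
    P plane."""
    observed = np.asarray(observed, dtype=float)
    _check_noncollinear(observed)
    p, c4, n = observed
    e1 = n - c4
    e1 = e1 / np.linalg.norm(e1)
    v2 = p - c4
    e2 = v2 - (v2 @ e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    return RigidFrame(np.stack([e1, e2, e3], axis=1), c4)


def frames_from_structure(beads: BeadStructure, sequence) -> FrameSet:
    """Per-residue frames from bead triads via SVD orthogonalization."""
    templates = derive_templates()
    frames = []
    for i, base in enumerate(sequence):
        f, _ = frame_from_beads(beads.coords[i], templates[base])
        frames.append(f)
    return FrameSet.from_frames(frames)


# ---------------------------------------------------------------------------
# full-atom structures


@dataclass
class FullAtomStructure:
    """A single-chain full-atom RNA structure (heavy atoms)."""

    res_names: list  # L residue names (A/U/G/C)
    atom_names: list  # L lists of atom names
    coords: list = field(repr=False)  # L arrays (n_i, 3)
    chain_id: str = "A"

    def __post_init__(self):
        self.coords = [np.asarray(c, dtype=float) for c in self.coords]
        if not (len(self.res_names) == len(self.atom_names) == len(self.coords)):
            raise ValueError("per-residue lists must have equal length")

    def __len__(self):
        return len(self.res_names)

    @property
    def n_atoms(self) -> int:
        return sum(len(c) for c in self.coords)

    def atom_coord(self, i: int, name: str) -> np.ndarray:
        return self.coords[i][self.atom_names[i].index(name)]

    def to_beads(self) -> BeadStructure:
        """Extract (P, C4', glycosidic N) bead coordinates; residues
        missing any bead atom are masked out."""
        L = len(self)
        coords = np.zeros((L, 3, 3))
        mask = np.ones(L, dtype=bool)
        for i, base in enumerate(self.res_names):
            names = (("P", "C4'", GLYCOSIDIC_N[base]))
            for a, nm in enumerate(names):
                if nm in self.atom_names[i]:
                    coords[i, a] = self.atom_coord(i, nm)
                else:
                    mask[i] = False
        return BeadStructure(coords, mask)

    def all_coords(self) -> np.ndarray:
        return np.concatenate(self.coords, axis=0)

    def copy(self) -> "FullAtomStructure":
        return FullAtomStructure(
            list(self.res_names),
            [list(a) for a in self.atom_names],
            [c.copy() for c in self.coords],
            self.chain_id,
        )


# ---------------------------------------------------------------------------
# idealized nucleotide geometry

_BACKBONE_ATOMS = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'",
    "O2'", "C1'",
)


@lru_cache(maxsize=None)
def _ccd_nucleotide(base: str):
    """Heavy-atom idealized geometry of one ribonucleotide, as a dict
    name -> 3-vector, from the chemical component dictionary."""
    import biotite.structure.info as bsinfo

    res = bsinfo.residue(base)
    out = {}
    for name, elem, xyz in zip(res.atom_name, res.element, res.coord):
        if elem == "H" or name == "OP3":
            continue
        out[str(name)] = np.asarray(xyz, dtype=float)
    return out


@lru_cache(maxsize=None)
def _grafted_nucleotides():
    """All four nucleotides sharing one common sugar-phosphate backbone.

    The 'A' backbone is the reference; each base is carried over by
    superposing its own sugar-phosphate atoms onto the reference ones.
    Returns dict base -> (atom_names tuple, coords array).
    """
    ref = _ccd_nucleotide("A")
    ref_bb = np.stack([ref[a] for a in _BACKBONE_ATOMS])
    out = {}
    for base in "AUGC":
        nt = _ccd_nucleotide(base)
        bb = np.stack([nt[a] for a in _BACKBONE_ATOMS])
        R, t, _ = kabsch(bb, ref_bb)
        names = list(_BACKBONE_ATOMS)
        coords = [ref[a].copy() for a in _BACKBONE_ATOMS]
        for name, xyz in nt.items():
            if name not in _BACKBONE_ATOMS:
                names.append(name)
                coords.append(R @ xyz + t)
        out[base] = (tuple(names), np.stack(coords))
    return out


def _helix_symmetry() -> RigidFrame:
    """One helical step: rotation by the twist about +z plus the rise."""
    th = np.deg2rad(HELIX_TWIST_DEG)
    Rz = np.array(
        [[np.cos(th), -np.sin(th), 0.0], [np.sin(th), np.cos(th), 0.0], [0, 0, 1.0]]
    )
    return RigidFrame(Rz, np.array([0.0, 0.0, HELIX_RISE]))


_DYAD = RigidFrame(np.diag([1.0, -1.0, -1.0]), np.zeros(3))  # pi about x


def _rotvec_to_matrix(w: np.ndarray) -> np.ndarray:
    th = np.linalg.norm(w)
    if th < 1e-12:
        return np.eye(3)
    k = w / th
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * K @ K


def _rotate_group(xyz, idx, axis_a, axis_b, angle):
    """Rotate the atoms ``idx`` about the bond axis_a -> axis_b."""
    u = xyz[axis_b] - xyz[axis_a]
    u = u / np.linalg.norm(u)
    K = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    R = np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * K @ K
    xyz[idx] = (xyz[idx] - xyz[axis_a]) @ R.T + xyz[axis_a]


def _flex_nucleotide(base: str, torsions, chi: float):
    """Grafted nucleotide with backbone torsion groups and the
    glycosidic rotation ``chi`` applied.  Torsions rotate, in order:
    the phosphate arm about C4'-C5' and C5'-O5', the OP1/OP2 pair about
    O5'-P, and O3' about C4'-C3'."""
    names, xyz = _grafted_nucleotides()[base]
    names = list(names)
    xyz = xyz.copy()
    idx = {n: i for i, n in enumerate(names)}
    t_gamma, t_beta, t_alpha, t_o3 = torsions
    _rotate_group(xyz, [idx[a] for a in ("O5'", "P", "OP1", "OP2")],
                  idx["C4'"], idx["C5'"], t_gamma)
    _rotate_group(xyz, [idx[a] for a in ("P", "OP1", "OP2")],
                  idx["C5'"], idx["O5'"], t_beta)
    _rotate_group(xyz, [idx[a] for a in ("OP1", "OP2")],
                  idx["O5'"], idx["P"], t_alpha)
    _rotate_group(xyz, [idx["O3'"]], idx["C4'"], idx["C3'"], t_o3)
    base_grp = [i for i, n in enumerate(names) if n not in _BACKBONE_ATOMS]
    _rotate_group(xyz, base_grp, idx["C1'"], idx[GLYCOSIDIC_N[base]], chi)
    return names, xyz


# Converged solution of :func:`solve_helix_placement`: rigid placement
# (rotation vector, translation), four backbone torsions, and per-base
# glycosidic rotations chi(A), chi(U), chi(G), chi(C).  Regenerate with
# solve_helix_placement() after changing the objective.
_PLACEMENT_X = np.array([
    2.20231365, -4.11049589, 0.82898562,         # rotation vector of g
    12.35128914, -2.11105435, 4.05967704,        # translation of g
    -0.95775693, 0.15183762, 1.13654542, -1.68743039,  # backbone torsions
    -2.75556406, -0.29054013, -2.76131668, -0.42053187,  # chi A,U,G,C
])

#: canonical hydrogen-bond atom pairs and lengths across the dyad
_WC_BONDS = {
    "A": ("U", (("N1", "N3", 2.82), ("N6", "O4", 2.95))),
    "G": ("C", (("N1", "N3", 2.95), ("O6", "N4", 2.91), ("N2", "O2", 2.86))),
}

_RING_6 = ("N1", "C2", "N3", "C4", "C5", "C6")


def _base_plane_normal(xyz, idx):
    pts = np.stack([xyz[idx[a]] for a in _RING_6])
    pts = pts - pts.mean(axis=0)
    return np.linalg.svd(pts)[2][2]


def _placement_residuals(x):
    """Least-squares residuals of the helical placement problem: O3'-P
    backbone continuity (1.6 A) on both strands under the 32.7 deg /
    2.548 A helical symmetry, Watson-Crick hydrogen-bond distances and
    base coplanarity for A-U and G-C across the dyad, weak A-form priors
    (P radius 9.4 A, C1'-C1' 10.4 A, P-P step 5.9 A), steric hinges for
    stacked neighbors and paired strands, and torsion regularization."""
    S = _helix_symmetry()
    D = _DYAD
    g = RigidFrame(_rotvec_to_matrix(x[:3]), x[3:6])
    tors = x[6:10]
    chi = {"A": x[10], "U": x[11], "G": x[12], "C": x[13]}
    nts = {}
    for b in "AUGC":
        names, xyz = _flex_nucleotide(b, tors, chi[b])
        nts[b] = ({n: i for i, n in enumerate(names)}, xyz)
    ia, xa = nts["A"]
    iu, xu = nts["U"]
    A1 = g.apply(xa)
    A1n = S.compose(g).apply(xa)
    B1u = D.compose(g).apply(xu)
    B0u = S.compose(D.compose(g)).apply(xu)
    res = [
        8.0 * (np.linalg.norm(A1[ia["O3'"]] - A1n[ia["P"]]) - 1.6),
        8.0 * (np.linalg.norm(B0u[iu["O3'"]] - B1u[iu["P"]]) - 1.6),
        0.3 * (np.linalg.norm(A1[ia["P"]][:2]) - 9.4),
        0.3 * (np.linalg.norm(A1[ia["C1'"]] - B1u[iu["C1'"]]) - 10.4),
        0.3 * (np.linalg.norm(A1[ia["P"]] - A1n[ia["P"]]) - 5.9),
    ]
    for pur, (pyr, bonds) in _WC_BONDS.items():
        ip, xp = nts[pur]
        iy, xy = nts[pyr]
        P1 = g.apply(xp)
        Y1 = D.compose(g).apply(xy)
        excl = []
        for a, b, d0 in bonds:
            res.append(2.0 * (np.linalg.norm(P1[ip[a]] - Y1[iy[b]]) - d0))
            excl.append((ip[a], iy[b]))
        res.append(
            1.2 * (abs(_base_plane_normal(P1, ip) @ _base_plane_normal(Y1, iy)) - 1.0)
        )
        d_pair = np.linalg.norm(P1[:, None, :] - Y1[None, :, :], axis=-1)
        for e in excl:
            d_pair[e] = 10.0
        if pur == "A":
            d_pair[ip["C2"], iy["O2"]] = 10.0
        res.append(3.0 * np.sqrt((np.clip(2.75 - d_pair, 0, None) ** 2).sum()))
    for b1 in "AUGC":
        i1, x1 = nts[b1]
        X1 = g.apply(x1)
        for b2 in "AUGC":
            i2, x2 = nts[b2]
            X2 = S.compose(g).apply(x2)
            dd = np.linalg.norm(X1[:, None, :] - X2[None, :, :], axis=-1)
            dd[i1["O3'"], i2["P"]] = 10.0
            res.append(2.0 * np.sqrt((np.clip(3.0 - dd, 0, None) ** 2).sum()))
            X2c = S.compose(D.compose(g)).apply(x2)
            dd = np.linalg.norm(X1[:, None, :] - X2c[None, :, :], axis=-1)
            res.append(1.0 * np.sqrt((np.clip(2.85 - dd, 0, None) ** 2).sum()))
    res.extend(0.05 * np.asarray(x[6:10]))
    return np.array(res)


def solve_helix_placement(n_starts: int = 6, seed: int = 0) -> np.ndarray:
    """Re-derive :data:`_PLACEMENT_X` by seeded multi-start least
    squares (slow; development utility, not used at import time)."""
    from scipy.optimize import least_squares

    rng = np.random.default_rng(seed)
    best = None
    starts = [_PLACEMENT_X] + [
        _PLACEMENT_X
        + np.concatenate([rng.normal(size=10) * 0.15, rng.normal(size=4) * 0.3])
        for _ in range(max(0, n_starts - 1))
    ]
    for x0 in starts:
        sol = least_squares(_placement_residuals, x0, xtol=1e-12, ftol=1e-12,
                            max_nfev=1200)
        if best is None or sol.cost < best.cost:
            best = sol
    return best.x


@lru_cache(maxsize=None)
def _helix_placement() -> RigidFrame:
    """Rigid placement g of the nucleotide within the helix frame."""
    x = _PLACEMENT_X
    return RigidFrame(_rotvec_to_matrix(x[:3]), x[3:6])


@lru_cache(maxsize=None)
def _helix_nucleotides():
    """Per-base nucleotide conformations used throughout the builder:
    the grafted nucleotides with the solved backbone torsions and
    per-base glycosidic rotations applied."""
    tors = _PLACEMENT_X[6:10]
    chi = {"A": _PLACEMENT_X[10], "U": _PLACEMENT_X[11],
           "G": _PLACEMENT_X[12], "C": _PLACEMENT_X[13]}
    out = {}
    for base in "AUGC":
        names, xyz = _flex_nucleotide(base, tors, chi[base])
        out[base] = (tuple(names), xyz)
    return out


def _place_nucleotide(base: str, frame: RigidFrame):
    names, xyz = _helix_nucleotides()[base]
    return list(names), frame.apply(xyz)


# ---------------------------------------------------------------------------
# templates


@lru_cache(maxsize=None)
def _template_cache():
    g = _helix_placement()
    out = {}
    for base in "AUGC":
        names, xyz = _place_nucleotide(base, g)
        idx = {n: i for i, n in enumerate(names)}
        triad = np.stack(
            [xyz[idx["P"]], xyz[idx["C4'"]], xyz[idx[GLYCOSIDIC_N[base]]]]
        )
        centered = triad - triad.mean(axis=0)
        # express in the symmetric-orthogonalized local frame
        R = proper_orthogonalize(centered.T @ np.eye(3))
        local = centered @ R
        out[base] = NucleotideTemplate(base, local - local.mean(axis=0))
    out["N"] = NucleotideTemplate("N", out["U"].local_coords.copy())
    return out


def derive_templates() -> dict:
    """Predefined local 3-atom conformations, one per base type.

    Each template is the (P, C4', glycosidic N) triad of that nucleotide
    in the ideal A-form helix, centered on its centroid and expressed in
    its own symmetric-orthogonalized frame.  'N' aliases 'U'.
    """
    return dict(_template_cache())


# ---------------------------------------------------------------------------
# ideal helix / nested-structure builder


class CrossingPairError(ValueError):
    """The builder only handles nested (pseudoknot-free) pair tables."""


def _check_nested(pairs) -> None:
    ps = sorted(tuple(sorted(p)) for p in pairs)
    seen = set()
    for p in ps:
        if p[0] == p[1]:
            raise ValueError(f"residue paired with itself: {p}")
        for q in (p[0], p[1]):
            if q in seen:
                raise ValueError(f"residue {q} appears in more than one pair")
            seen.add(q)
    for i in range(len(ps)):
        for j in range(i + 1, len(ps)):
            a, b = ps[i]
            c, d = ps[j]
            if a < c < b < d:
                raise CrossingPairError(
                    f"crossing base pairs {ps[i]} and {ps[j]} (pseudoknot)"
                )


def _region_items(lo: int, hi: int, partner: dict):
    """Decompose [lo, hi] into unpaired indices and maximal helices."""
    items = []
    i = lo
    while i <= hi:
        j = partner.get(i)
        if j is None or j < i:
            items.append(("nt", i))
            i += 1
            continue
        # maximal stack of consecutive pairs
        h = 1
        while (
            partner.get(i + h) == j - h and j - h > i + h
        ):
            h += 1
        items.append(("helix", i, j, h))
        i = j + 1
    return items


@lru_cache(maxsize=None)
def _c4_ref() -> np.ndarray:
    """C4' position shared by all helix nucleotides (common backbone)."""
    names, xyz = _helix_nucleotides()["A"]
    return xyz[names.index("C4'")]


@lru_cache(maxsize=None)
def _g_centered() -> RigidFrame:
    """Nucleotide placement with its C4' at the frame origin (for loop
    and free-chain residues, where no helix axis exists)."""
    g = _helix_placement()
    return RigidFrame(g.rotation, -g.rotation @ _c4_ref())


def _loop_frame_step(unwound: float = 15.0):
    """Walk step for one unpaired residue: advance and gently turn."""
    th = np.deg2rad(unwound)
    Rz = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
    )
    return RigidFrame(Rz, np.array([0.0, 6.0, 0.0]))


def _helix_entry() -> RigidFrame:
    """Orient a child helix axis along the walk's +y direction."""
    # rotate +z onto +y
    R = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
    return RigidFrame(R, np.array([0.0, 4.0, 0.0]))


def _helix_exit(h: int, turn_deg: float) -> RigidFrame:
    """Walk update after traversing a helix of h pairs and returning:
    step sideways past the duplex footprint, then turn."""
    th = np.deg2rad(turn_deg)
    Rz = np.array(
        [[np.cos(th), -np.sin(th), 0], [np.sin(th), np.cos(th), 0], [0, 0, 1.0]]
    )
    return RigidFrame(Rz, np.array([24.0, 0.0, 0.0]))


def _arc_points(a: np.ndarray, b: np.ndarray, up: np.ndarray, n: int) -> np.ndarray:
    """n points on a circular arc from a to b bulging along ``up``,
    sized so consecutive points sit ~6 A apart (one backbone step)."""
    chord = b - a
    cl = np.linalg.norm(chord)
    if cl < 1e-9:
        u = np.array([1.0, 0.0, 0.0])
        cl = 1e-6
    else:
        u = chord / cl
    upn = up - (up @ u) * u
    nu = np.linalg.norm(upn)
    if nu < 1e-9:
        upn = np.array([0.0, 0.0, 1.0]) - u[2] * u
        nu = np.linalg.norm(upn)
    upn = upn / nu
    mid = 0.5 * (a + b)
    # circle radius from the desired arc length (~6 A per residue)
    rc = max((n + 1) * 6.0 / (2 * np.pi), cl / 2 + 0.2)
    h = np.sqrt(max(rc**2 - (cl / 2) ** 2, 0.04))
    center = mid + h * upn
    # plane coordinates: a = (-cl/2, -h), b = (+cl/2, -h)
    th_a = np.arctan2(-h, -cl / 2)
    th_b = np.arctan2(-h, cl / 2)
    span = 2 * np.pi - ((th_b - th_a) % (2 * np.pi))
    ts = np.linspace(0.0, 1.0, n + 2)[1:-1]
    th = th_a - ts * span
    return center[None, :] + rc * (
        np.cos(th)[:, None] * u[None, :] + np.sin(th)[:, None] * upn[None, :]
    )


@lru_cache(maxsize=None)
def _loop_local_basis() -> np.ndarray:
    """Orthonormal basis of the centered nucleotide built from its
    P->O3' (backbone direction) and C4'->N1/N9 (base direction)."""
    names, xyz = _helix_nucleotides()["A"]
    idx = {n: i for i, n in enumerate(names)}
    u1 = xyz[idx["O3'"]] - xyz[idx["P"]]
    u1 = u1 / np.linalg.norm(u1)
    u2 = xyz[idx["N9"]] - xyz[idx["C4'"]]
    u2 = u2 - (u2 @ u1) * u1
    u2 = u2 / np.linalg.norm(u2)
    return np.stack([u1, u2, np.cross(u1, u2)], axis=1)


def _nt_frame_at(point: np.ndarray, tangent: np.ndarray, outward: np.ndarray):
    """A deterministic nucleotide frame at an arc point: backbone along
    the tangent, base pointing outward."""
    t = tangent / np.linalg.norm(tangent)
    n = outward - (outward @ t) * t
    nn = np.linalg.norm(n)
    if nn < 1e-9:
        n = np.array([0.0, 0.0, 1.0]) - t[2] * t
        nn = np.linalg.norm(n)
    n = n / nn
    b = np.cross(t, n)
    basis_global = np.stack([t, n, b], axis=1)
    R = basis_global @ _loop_local_basis().T
    return RigidFrame(R, point - R @ _c4_ref())


def build_ideal_helix(
    sequence,
    pair_table,
    turn_deg: float = 120.0,
):
    """Build an idealized 3D structure for a nested secondary structure.

    Paired stems are regular A-form duplexes (32.7 degree twist, 2.548 A
    rise per step); unpaired stretches are placed on smooth connecting
    arcs; successive helices in open regions are placed with a
    configurable turn angle.  Returns ``(FullAtomStructure,
    BeadStructure)``.

    Raises :class:`CrossingPairError` for pseudoknotted pair tables.
    """
    if not isinstance(sequence, NucleotideSequence):
        sequence = NucleotideSequence(sequence)
    L = len(sequence)
    pairs = [tuple(sorted(p)) for p in pair_table]
    for a, b in pairs:
        if not (0 <= a < L and 0 <= b < L):
            raise ValueError(f"pair {(a, b)} out of range for L={L}")
    _check_nested(pairs)
    partner = {}
    for a, b in pairs:
        partner[a] = b
        partner[b] = a

    g = _helix_placement()
    S = _helix_symmetry()
    D = _DYAD
    placements: dict[int, RigidFrame] = {}

    def place_helix(entry: RigidFrame, a: int, b: int, h: int):
        step = RigidFrame.identity()
        for k in range(h):
            placements[a + k] = entry.compose(step).compose(g)
            placements[b - k] = entry.compose(step).compose(D).compose(g)
            step = S.compose(step)
        # enclosed region
        lo, hi = a + h, b - h
        if lo > hi:
            return
        inner = _region_items(lo, hi, partner)
        if all(it[0] == "nt" for it in inner):
            # hairpin loop: bridge the two stem ends on an arc
            base1 = sequence[a + h - 1] if sequence[a + h - 1] != "N" else "U"
            base2 = sequence[b - h + 1] if sequence[b - h + 1] != "N" else "U"
            end1 = placements[a + h - 1].apply(
                _helix_nucleotides()[base1][1][_BACKBONE_ATOMS.index("O3'")]
            )
            end2 = placements[b - h + 1].apply(
                _helix_nucleotides()[base2][1][_BACKBONE_ATOMS.index("P")]
            )
            axis = entry.rotation[:, 2]
            pts = _arc_points(end1, end2, axis, hi - lo + 1)
            mid = 0.5 * (end1 + end2)
            for m, i in enumerate(range(lo, hi + 1)):
                nxt = pts[m + 1] if m + 1 < len(pts) else end2
                outward = pts[m] - mid
                if np.linalg.norm(outward) < 1e-9:
                    outward = axis
                placements[i] = _nt_frame_at(pts[m], nxt - pts[m] + 1e-9, outward)
        else:
            # internal/multibranch loop: continue the walk from the far
            # end of the helix
            walk = entry.compose(
                RigidFrame(np.eye(3), np.array([0.0, 0.0, h * HELIX_RISE + 2.0]))
            )
            place_region(walk, inner)

    def place_region(walk: RigidFrame, items):
        for it in items:
            if it[0] == "nt":
                placements[it[1]] = walk.compose(_g_centered())
                walk = walk.compose(_loop_frame_step())
            else:
                _, a, b, h = it
                place_helix(walk.compose(_helix_entry()), a, b, h)
                walk = walk.compose(_helix_exit(h, turn_deg))
        return walk

    place_region(RigidFrame.identity(), _region_items(0, L - 1, partner))

    res_names, atom_names, coords = [], [], []
    for i in range(L):
        base = sequence[i] if sequence[i] != "N" else "U"
        names, xyz = _place_nucleotide(base, placements[i])
        res_names.append(base)
        atom_names.append(names)
        coords.append(xyz)
    full = FullAtomStructure(res_names, atom_names, coords)
    return full, full.to_beads()
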