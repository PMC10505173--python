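"""RNA model-quality metrics: P-atom RMSD, TM-score, INF, DI,
Handedness, and a heavy-atom clash estimate.

TM-score uses the RNA length-dependent normalization distance d0 and an
iterative fragment-seeded superposition search; it is invariant to rigid
motions of either structure and symmetric for equal-length 1:1 mappings.
INF (interaction network fidelity) is the Matthews correlation
coefficient between reference and predicted interaction sets over the
universe of residue pairs; DI (deformation index) is RMSD divided by the
overall INF.  Handedness is the fraction of non-loop (base-paired)
residues whose C4' pseudotorsion is closer, on the circle, to the
target's than to the target's mirror image -- mirrored models score 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import _dihedral_vec
from .geometry import BeadStructure, FullAtomStructure, RigidFrame, kabsch
from .secondary import SecondaryStructure

#: reduced heavy-atom contact radii (A): a coarse surrogate for
#: hydrogen-aware contact analysis, sized so canonical A-form stacking
#: and base-pair contacts are not flagged
VDW_RADII = {"C": 1.55, "N": 1.40, "O": 1.35, "P": 1.80}

#: clash threshold: pairs overlapping by at least this much (A)
CLASH_OVERLAP = 0.4

#: inter-residue backbone pairs excluded from clash counting (i, i+1)
_BACKBONE_LINK_EXCLUSIONS = {
    ("O3'", "P"), ("O3'", "OP1"), ("O3'", "OP2"), ("O3'", "O5'"), ("C3'", "P"),
}


# ---------------------------------------------------------------------------
# superposition metrics


def _atom_coords(s, atom: str) -> np.ndarray:
    if isinstance(s, BeadStructure):
        return s.atom(atom)
    return np.asarray(s, dtype=float)


def superpose_rmsd(a, b, atom: str = "P"):
    """Kabsch-optimal RMSD between two structures on one bead atom.

    Returns ``(rmsd, frame)`` where ``frame`` maps a onto b.
    """
    xa, xb = _atom_coords(a, atom), _atom_coords(b, atom)
    if xa.shape != xb.shape:
        raise ValueError("structures must have equal length")
    R, t, rmsd = kabsch(xa, xb)
    return rmsd, RigidFrame(R, t)


def d0_rna(L: int) -> float:
    """Length-dependent TM-score normalization distance for RNA."""
    if L <= 11:
        return 0.3
    if L <= 15:
        return 0.4
    if L <= 19:
        return 0.5
    if L <= 23:
        return 0.6
    if L < 30:
        return 0.7
    return 0.6 * np.sqrt(L - 0.5) - 2.5


def _tm_of_superposition(xm, xt, R, t, d0) -> float:
    d = np.linalg.norm(xm @ R.T + t - xt, axis=1)
    return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))


def tm_score(model, target, atom: str = "C4'") -> float:
    """TM-score in (0, 1] between equal-length structures (1:1 mapping).

    Maximized over superpositions by seeding Kabsch fits from sliding
    fragments (full, half, quarter length) and iteratively re-fitting on
    the residues closest after superposition.
    """
    xm, xt = _atom_coords(model, atom), _atom_coords(target, atom)
    if xm.shape != xt.shape:
        raise ValueError("structures must have equal length")
    L = len(xm)
    d0 = d0_rna(L)

    def score_of(R, t):
        d = np.linalg.norm(xm @ R.T + t - xt, axis=1)
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))

    best = 0.0
    best_Rt = (np.eye(3), np.zeros(3))
    cut_schedule = [8.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.5, 1.0, max(0.5, d0)]
    frag_lens = sorted({L, max(4, L // 2), max(4, L // 4)}, reverse=True)
    for fl in frag_lens:
        for s in range(0, L - fl + 1, max(1, fl // 2)):
            sel = np.arange(s, s + fl)
            R, t, _ = kabsch(xm[sel], xt[sel])
            for cut in cut_schedule:
                for _ in range(20):
                    d = np.linalg.norm(xm @ R.T + t - xt, axis=1)
                    sc = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
                    if sc > best:
                        best, best_Rt = sc, (R, t)
                    new = np.nonzero(d < cut)[0]
                    c = cut
                    while len(new) < 4:
                        c += 0.5
                        new = np.nonzero(d < c)[0]
                    if np.array_equal(new, sel):
                        break
                    sel = new
                    R, t, _ = kabsch(xm[sel], xt[sel])
    # local 6-dof polish of the best superposition found
    from scipy.optimize import minimize
    from scipy.spatial.transform import Rotation

    R0, t0 = best_Rt
    rv0 = Rotation.from_matrix(R0).as_rotvec()

    def neg(x):
        return -score_of(Rotation.from_rotvec(x[:3]).as_matrix(), x[3:])

    res = minimize(neg, np.concatenate([rv0, t0]), method="Nelder-Mead",
                   options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-9})
    return max(best, -float(res.fun))


# ---------------------------------------------------------------------------
# interaction metrics


@dataclass
class InteractionSet:
    """Residue-pair interactions of one category."""

    category: str  # "WC" | "nWC" | "stacking"
    pairs: set

    def __post_init__(self):
        if self.category not in ("WC", "nWC", "stacking"):
            raise ValueError(f"unknown interaction category {self.category!r}")
        self.pairs = {tuple(sorted(p)) for p in self.pairs}
        for i, j in self.pairs:
            if i == j or i < 0:
                raise ValueError(f"invalid interaction pair {(i, j)}")


def _confusion(ref: set, pred: set, L: int):
    universe = L * (L - 1) // 2
    tp = len(ref & pred)
    fp = len(pred - ref)
    fn = len(ref - pred)
    tn = universe - tp - fp - fn
    return tp, fp, fn, tn


def _mcc(tp, fp, fn, tn) -> float:
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def inf_score(
    ref, pred, L: int, category: str = "all", variant: str = "mcc"
):
    """Interaction network fidelity between reference and predicted
    interaction sets.

    ``ref`` and ``pred`` are iterables of :class:`InteractionSet`;
    ``category`` selects one category or pools them all.  The default
    variant is the Matthews correlation coefficient over the pair
    universe; ``variant="ppv_tpr"`` gives the sqrt(PPV*TPR) convention.
    Returns None when the selected reference category is empty.
    """
    ref = list(ref if not isinstance(ref, InteractionSet) else [ref])
    pred = list(pred if not isinstance(pred, InteractionSet) else [pred])

    def pool(sets):
        if category == "all":
            out = set()
            for s in sets:
                out |= s.pairs
            return out
        out = set()
        for s in sets:
            if s.category == category:
                out |= s.pairs
        return out

    r, p = pool(ref), pool(pred)
    if not r:
        return None
    tp, fp, fn, tn = _confusion(r, p, L)
    if variant == "mcc":
        return float(_mcc(tp, fp, fn, tn))
    if variant == "ppv_tpr":
        if tp + fp == 0 or tp + fn == 0:
            return 0.0
        return float(np.sqrt((tp / (tp + fp)) * (tp / (tp + fn))))
    raise ValueError(f"unknown INF variant {variant!r}")


def di_score(rmsd: float, inf_all: float) -> float:
    """Deformation index: RMSD divided by the overall INF."""
    if inf_all <= 0:
        raise ValueError("DI is undefined for INF <= 0")
    return rmsd / inf_all


# ---------------------------------------------------------------------------
# handedness


def c4_pseudotorsions(s: BeadStructure) -> np.ndarray:
    """Per-residue C4' pseudotorsion tau(i) over the window
    (i-1, i, i+1, i+2); NaN where undefined."""
    x = s.atom("C4'")
    L = len(x)
    out = np.full(L, np.nan)
    if L >= 4:
        out[1 : L - 2] = _dihedral_vec(x[:-3], x[1:-2], x[2:-1], x[3:])
    return out


def _circ_dist(a, b):
    d = np.abs(a - b) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def handedness(model: BeadStructure, target: BeadStructure, ss: SecondaryStructure):
    """Fraction of non-loop residues whose model pseudotorsion is closer
    to the target's than to the mirrored target's (which negates every
    torsion).  Ties count as "not closer".  Returns None when no residue
    is eligible."""
    if len(model) != len(target):
        raise ValueError("structures must have equal length")
    tau_m = c4_pseudotorsions(model)
    tau_t = c4_pseudotorsions(target)
    from .secondary import classify_loops

    nonloop = classify_loops(ss, len(model))
    eligible = nonloop & ~np.isnan(tau_m) & ~np.isnan(tau_t)
    if not eligible.any():
        return None
    dm = _circ_dist(tau_m[eligible], tau_t[eligible])
    dmir = _circ_dist(tau_m[eligible], -tau_t[eligible])
    return float(np.mean(dm < dmir))


# ---------------------------------------------------------------------------
# clashes


def clash_violations(s: FullAtomStructure):
    """Pairs of non-bonded heavy atoms overlapping by at least 0.4 A
    (sum of van der Waals radii minus distance)."""
    from scipy.spatial import cKDTree

    coords = s.all_coords()
    names, res, elems = [], [], []
    for i, (ans, xyz) in enumerate(zip(s.atom_names, s.coords)):
        for name in ans:
            names.append(name)
            res.append(i)
            elems.append(name[0] if name[0] in VDW_RADII else "C")
    radii = np.array([VDW_RADII[e] for e in elems])
    tree = cKDTree(coords)
    out = []
    for a, b in tree.query_pairs(2 * max(VDW_RADII.values())):
        if res[a] == res[b]:
            continue
        if abs(res[a] - res[b]) == 1:
            lo, hi = (a, b) if res[a] < res[b] else (b, a)
            if (names[lo], names[hi]) in _BACKBONE_LINK_EXCLUSIONS:
                continue
        overlap = radii[a] + radii[b] - np.linalg.norm(coords[a] - coords[b])
        if overlap >= CLASH_OVERLAP:
            out.append((min(a, b), max(a, b), float(overlap)))
    return out


def clash_estimate(s: FullAtomStructure) -> float:
    """Clashing atom pairs per 1000 atoms."""
    return 1000.0 * len(clash_violations(s)) / max(1, s.n_atoms)


# ---------------------------------------------------------------------------
# Watson-Crick detection (geometric, for self-generated fixtures)

_WC_ATOMS = {"A": "N1", "G": "N1", "U": "N3", "C": "N3"}
_RING_ATOMS = ("N1", "C2", "N3", "C4", "C5", "C6")


def _base_normal(s: FullAtomStructure, i: int) -> np.ndarray:
    pts = np.stack(
        [s.atom_coord(i, a) for a in _RING_ATOMS if a in s.atom_names[i]]
    )
    pts = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts)
    return vt[2]


def detect_wc_pairs(
    s: FullAtomStructure, max_dist: float = 3.5, max_plane_deg: float = 60.0
) -> InteractionSet:
    """Detect canonical Watson-Crick pairs from coordinates.

    Criterion: complementary bases whose N1(purine)-N3(pyrimidine)
    distance is below ``max_dist`` with base planes within
    ``max_plane_deg`` of parallel.  Each residue keeps only its closest
    partner.
    """
    from .geometry import WC_CONJUGATE

    L = len(s)

    def usable(i):
        base = s.res_names[i]
        names = s.atom_names[i]
        return _WC_ATOMS.get(base) in names and sum(
            a in names for a in _RING_ATOMS
        ) >= 3

    cand = []
    for i in range(L):
        if not usable(i):
            continue
        for j in range(i + 1, L):
            if not usable(j):
                continue
            bi, bj = s.res_names[i], s.res_names[j]
            if WC_CONJUGATE.get(bi) != bj:
                continue
            d = np.linalg.norm(
                s.atom_coord(i, _WC_ATOMS[bi]) - s.atom_coord(j, _WC_ATOMS[bj])
            )
            if d > max_dist:
                continue
            cosang = abs(_base_normal(s, i) @ _base_normal(s, j))
            if cosang < np.cos(np.deg2rad(max_plane_deg)):
                continue
            cand.append((d, i, j))
    cand.sort()
    used, pairs = set(), set()
    for d, i, j in cand:
        if i in used or j in used:
            continue
        used |= {i, j}
        pairs.add((i, j))
    return InteractionSet("WC", pairs)
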