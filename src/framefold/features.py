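"""Inter-nucleotide geometry terms: distances, long-range dihedrals,
and their discretization into bins.

Six terms are measured between every ordered residue pair (i, j):

* three bead-bead distances, binned uniformly with two extra bins
  (below 2 A; at or beyond the term's maximum M):

  ========  ======  ============  =========
  term      atoms   content bins  range (A)
  ========  ======  ============  =========
  dist_PP   P-P     56            [2, 30]
  dist_CC   C4'-C4' 44            [2, 24]
  dist_NN   N-N     32            [2, 18]
  ========  ======  ============  =========

* three long-range dihedrals over atom quadruples of the pair, binned
  into 36 uniform angular bins on (-pi, pi] plus one extra bin used when
  the central virtual bond of the quadruple is at or beyond its maximum
  distance M (C4'-C4' with M = 24 A for PCCP; N-N with M = 18 A for
  CNNC and PNNP):

  ========  =======================================
  term      quadruple
  ========  =======================================
  dih_PCCP  P(i) - C4'(i) - C4'(j) - P(j)
  dih_CNNC  C4'(i) - N(i) - N(j) - C4'(j)
  dih_PNNP  P(i) - N(i) - N(j) - P(j)
  ========  =======================================

The separate 38-bin inter-N distance scheme (36 uniform bins over
[2, 40] A plus the two extras) supports the end-to-end distance loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BeadStructure

MASKED_LABEL = -1


@dataclass(frozen=True)
class GeometryBinSpec:
    """Binning of one geometry term."""

    name: str
    kind: str  # "distance" | "dihedral"
    atoms: tuple  # atom names defining the term
    n_content: int
    lo: float
    hi: float
    gate_atom: str = None  # dihedral only: virtual-bond atom
    gate_max: float = None  # dihedral only: M for the virtual bond

    @property
    def n_total(self) -> int:
        # distances: below-range + content + beyond-range
        # dihedrals: content + single beyond-M bin
        return self.n_content + (2 if self.kind == "distance" else 1)

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_content

    def content_centers(self) -> np.ndarray:
        w = self.bin_width
        return self.lo + w * (0.5 + np.arange(self.n_content))

    def edges(self) -> np.ndarray:
        return self.lo + self.bin_width * np.arange(self.n_content + 1)


DIST_PP = GeometryBinSpec("dist_PP", "distance", ("P", "P"), 56, 2.0, 30.0)
DIST_CC = GeometryBinSpec("dist_CC", "distance", ("C4'", "C4'"), 44, 2.0, 24.0)
DIST_NN = GeometryBinSpec("dist_NN", "distance", ("N", "N"), 32, 2.0, 18.0)
DIH_PCCP = GeometryBinSpec(
    "dih_PCCP", "dihedral", ("P", "C4'", "C4'", "P"), 36, -np.pi, np.pi,
    gate_atom="C4'", gate_max=24.0,
)
DIH_CNNC = GeometryBinSpec(
    "dih_CNNC", "dihedral", ("C4'", "N", "N", "C4'"), 36, -np.pi, np.pi,
    gate_atom="N", gate_max=18.0,
)
DIH_PNNP = GeometryBinSpec(
    "dih_PNNP", "dihedral", ("P", "N", "N", "P"), 36, -np.pi, np.pi,
    gate_atom="N", gate_max=18.0,
)

#: the six geometry terms, in their fixed serialization order
GEOMETRY_TERMS = {
    s.name: s for s in (DIST_PP, DIST_CC, DIST_NN, DIH_PCCP, DIH_CNNC, DIH_PNNP)
}

#: inter-N distance bins of the end-to-end distance loss (38 bins total)
E2E_DIST_SPEC = GeometryBinSpec(
    "dist_NN_e2e", "distance", ("N", "N"), 36, 2.0, 40.0
)


# ---------------------------------------------------------------------------
# measurement


def pairwise_distances(s: BeadStructure, atom: str) -> np.ndarray:
    """L x L Euclidean distances between one bead atom across residues.

    Symmetric with a zero diagonal; entries involving masked residues
    are NaN.
    """
    x = s.atom(atom)
    d = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    bad = ~s.mask
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    np.fill_diagonal(d, np.where(s.mask, 0.0, np.nan))
    return d


def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle in (-pi, pi], IUPAC sign convention."""
    return float(_dihedral_vec(*(np.asarray(p)[None, :] for p in (p1, p2, p3, p4)))[0])


def _dihedral_vec(p1, p2, p3, p4) -> np.ndarray:
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    m1 = np.cross(n1, b2n)
    x = (n1 * n2).sum(axis=-1)
    y = (m1 * n2).sum(axis=-1)
    out = np.arctan2(y, x)
    # map -pi to +pi so the range is (-pi, pi]
    out[out <= -np.pi] = np.pi
    return out


def pair_dihedral(s: BeadStructure, i: int, j: int, scheme: str) -> float:
    """The long-range dihedral of one ordered residue pair.

    ``scheme`` is one of PCCP, CNNC, PNNP.  Degenerate (collinear)
    quadruples return NaN, mapped to the extra bin downstream.
    """
    if i == j:
        raise ValueError("pair dihedral needs two distinct residues")
    spec = GEOMETRY_TERMS[f"dih_{scheme}"]
    a1, a2, a3, a4 = spec.atoms
    from .geometry import BEAD_ATOMS

    p1 = s.coords[i, BEAD_ATOMS.index(a1)]
    p2 = s.coords[i, BEAD_ATOMS.index(a2)]
    p3 = s.coords[j, BEAD_ATOMS.index(a3)]
    p4 = s.coords[j, BEAD_ATOMS.index(a4)]
    b2 = p3 - p2
    n1 = np.cross(p2 - p1, b2)
    n2 = np.cross(b2, p4 - p3)
    if np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return float("nan")
    return dihedral(p1, p2, p3, p4)


def pair_dihedrals(s: BeadStructure, scheme: str) -> np.ndarray:
    """L x L matrix of one dihedral term over all ordered pairs (NaN on
    the diagonal and for masked/degenerate entries)."""
    from .geometry import BEAD_ATOMS

    spec = GEOMETRY_TERMS[f"dih_{scheme}"]
    a1, a2, a3, a4 = (BEAD_ATOMS.index(a) for a in spec.atoms)
    L = len(s)
    p1 = np.broadcast_to(s.coords[:, a1][:, None, :], (L, L, 3))
    p2 = np.broadcast_to(s.coords[:, a2][:, None, :], (L, L, 3))
    p3 = np.broadcast_to(s.coords[:, a3][None, :, :], (L, L, 3))
    p4 = np.broadcast_to(s.coords[:, a4][None, :, :], (L, L, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = _dihedral_vec(p1, p2, p3, p4)
    np.fill_diagonal(out, np.nan)
    bad = ~s.mask
    out[bad, :] = np.nan
    out[:, bad] = np.nan
    return out


# ---------------------------------------------------------------------------
# discretization


def discretize_distances(values: np.ndarray, spec: GeometryBinSpec) -> np.ndarray:
    """Bin indices for distance values.

    Half-open bins [edge, edge + width); values below ``lo`` go to the
    first extra bin (index 0), values at or beyond ``hi`` to the last.
    NaN entries are labeled :data:`MASKED_LABEL`.
    """
    if spec.kind != "distance":
        raise ValueError("spec must be a distance term")
    v = np.asarray(values, dtype=float)
    out = np.empty(v.shape, dtype=int)
    nan = np.isnan(v)
    vv = np.where(nan, spec.lo, v)
    # 1e-9 snap so values on a (float-inexact) bin edge land on its right
    idx = np.floor((vv - spec.lo) / spec.bin_width + 1e-9).astype(int) + 1
    idx = np.clip(idx, 1, spec.n_content)
    out[:] = idx
    out[vv < spec.lo] = 0
    out[vv >= spec.hi] = spec.n_total - 1
    out[nan] = MASKED_LABEL
    return out


def discretize_dihedrals(
    values: np.ndarray, gate_distances: np.ndarray, spec: GeometryBinSpec
) -> np.ndarray:
    """Bin indices for dihedral values.

    36 uniform bins over (-pi, pi]; pairs whose gating virtual bond is
    at or beyond M (and degenerate/NaN angles of gated pairs) get the
    single extra bin regardless of angle.  NaN gate distances are
    labeled :data:`MASKED_LABEL`.
    """
    if spec.kind != "dihedral":
        raise ValueError("spec must be a dihedral term")
    v = np.asarray(values, dtype=float)
    gd = np.asarray(gate_distances, dtype=float)
    nan_gate = np.isnan(gd)
    beyond = gd >= spec.gate_max
    vv = np.where(np.isnan(v), 0.0, v)
    idx = np.floor((vv - spec.lo) / spec.bin_width + 1e-9).astype(int)
    idx = np.clip(idx, 0, spec.n_content - 1)
    out = np.where(beyond | np.isnan(v), spec.n_content, idx)
    out[nan_gate] = MASKED_LABEL
    return out.astype(int)


def discretize(values, spec: GeometryBinSpec, gate_distances=None) -> np.ndarray:
    if spec.kind == "distance":
        return discretize_distances(values, spec)
    if gate_distances is None:
        raise ValueError("dihedral discretization needs gate distances")
    return discretize_dihedrals(values, gate_distances, spec)


def geometry_labels(s: BeadStructure) -> dict:
    """Per-term L x L bin-index matrices for all six geometry terms.

    Diagonal and masked entries carry :data:`MASKED_LABEL`.
    """
    out = {}
    dists = {a: pairwise_distances(s, a) for a in ("P", "C4'", "N")}
    for name, spec in GEOMETRY_TERMS.items():
        if spec.kind == "distance":
            lab = discretize_distances(dists[spec.atoms[0]], spec)
        else:
            scheme = name.split("_")[1]
            lab = discretize_dihedrals(
                pair_dihedrals(s, scheme), dists[spec.gate_atom], spec
            )
        np.fill_diagonal(lab, MASKED_LABEL)
        out[name] = lab
    return out


def e2e_distance_labels(s: BeadStructure) -> np.ndarray:
    """38-bin inter-N distance labels for the end-to-end distance loss."""
    lab = discretize_distances(pairwise_distances(s, "N"), E2E_DIST_SPEC)
    np.fill_diagonal(lab, MASKED_LABEL)
    return lab
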