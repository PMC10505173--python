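"""Full-atom reconstruction from the 3-bead model, fast local fixes,
and an external-refinement hook.

Reconstruction places each residue's full-atom A-form nucleotide
template rigidly onto its (P, C4', N) bead triad.  Residues typed 'N'
are resolved first: unpaired ones become the smallest base U, paired
ones the Watson-Crick conjugate of their partner.  Fast fixes then
iteratively adjust non-bead atoms only -- pulling the O3'(i)-P(i+1)
linkage toward 1.6 A and relaxing steric overlaps below 2.0 A -- while
the bead atoms stay bitwise frozen.
"""

from __future__ import annotations

import subprocess
import tempfile
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import (
    GLYCOSIDIC_N,
    WC_CONJUGATE,
    BeadStructure,
    FullAtomStructure,
    NucleotideSequence,
    _helix_nucleotides,
    kabsch,
)
from .secondary import SecondaryStructure

#: O3'-P linkage: target length and the band treated as acceptable (A)
O3P_TARGET = 1.6
O3P_BAND = (1.3, 1.9)

#: heavy-atom pairs closer than this are treated as overlaps to relax (A)
CLASH_DIST = 2.0

REFINEMENT_K = 0.6  # empirical coefficient of the external-minimizer step count


class AmbiguousBaseError(ValueError):
    """An 'N' residue whose pairing does not determine a concrete base."""


def resolve_n_bases(sequence, ss: SecondaryStructure) -> list:
    """Concrete base types with every 'N' resolved: U when unpaired, the
    Watson-Crick conjugate of the partner when paired."""
    partner = ss.partner() if ss is not None else {}
    out = []
    for i, base in enumerate(sequence):
        if base != "N":
            out.append(base)
            continue
        j = partner.get(i)
        if j is None:
            out.append("U")
        else:
            pb = sequence[j]
            if pb == "N":
                raise AmbiguousBaseError(
                    f"'N' at {i} paired with 'N' at {j}: no conjugate defined"
                )
            out.append(WC_CONJUGATE[pb])
    return out


def reconstruct_full_atom(
    beads: BeadStructure, sequence, ss: SecondaryStructure = None
) -> FullAtomStructure:
    """Rigidly superpose each base type's full-atom template onto the
    residue's bead triad."""
    sequence = (
        sequence
        if isinstance(sequence, NucleotideSequence)
        else NucleotideSequence(sequence)
    )
    if len(beads) != len(sequence):
        raise ValueError("bead structure and sequence must have equal length")
    bases = resolve_n_bases(sequence, ss)
    res_names, atom_names, coords = [], [], []
    for i, base in enumerate(bases):
        names, xyz = _helix_nucleotides()[base]
        names = list(names)
        idx = {n: k for k, n in enumerate(names)}
        triad = np.stack(
            [xyz[idx["P"]], xyz[idx["C4'"]], xyz[idx[GLYCOSIDIC_N[base]]]]
        )
        R, t, _ = kabsch(triad, beads.coords[i])
        placed = xyz @ R.T + t
        # anchor the bead atoms exactly (the superposition is exact for
        # triads realized from the same template; this removes residual
        # float error for perturbed triads as well)
        for k, name in enumerate(("P", "C4'", GLYCOSIDIC_N[base])):
            placed[idx[name]] = beads.coords[i, k]
        res_names.append(base)
        atom_names.append(names)
        coords.append(placed)
    return FullAtomStructure(res_names, atom_names, coords)


# ---------------------------------------------------------------------------
# fast fixes


def _movable_mask(s: FullAtomStructure) -> list:
    masks = []
    for base, names in zip(s.res_names, s.atom_names):
        frozen = {"P", "C4'", GLYCOSIDIC_N[base]}
        masks.append(np.array([n not in frozen for n in names]))
    return masks


def _connectivity_violations(s: FullAtomStructure):
    out = []
    for i in range(len(s) - 1):
        d = np.linalg.norm(s.atom_coord(i, "O3'") - s.atom_coord(i + 1, "P"))
        if not (O3P_BAND[0] <= d <= O3P_BAND[1]):
            out.append((i, float(d)))
    return out


def _clash_pairs(s: FullAtomStructure):
    from scipy.spatial import cKDTree

    coords = s.all_coords()
    res = np.concatenate(
        [np.full(len(c), i) for i, c in enumerate(s.coords)]
    )
    names = [n for ans in s.atom_names for n in ans]
    tree = cKDTree(coords)
    pairs = []
    for a, b in tree.query_pairs(CLASH_DIST):
        if res[a] == res[b]:
            continue
        if abs(res[a] - res[b]) == 1:
            lo, hi = (a, b) if res[a] < res[b] else (b, a)
            if {names[lo], names[hi]} & {"O3'", "P", "O5'"} == {"O3'", "P"} or (
                names[lo] == "O3'" and names[hi] in ("P", "O5'", "OP1", "OP2")
            ):
                continue
        pairs.append((a, b))
    return pairs


def fast_fixes(s: FullAtomStructure, max_iter: int = 40):
    """Iterative local adjustment of non-bead atoms: backbone
    connectivity toward 1.6 A and steric overlaps below 2.0 A.  Bead
    atoms are bitwise unchanged.  Returns ``(fixed, report)`` with
    before/after violation counts; when no violations exist the input is
    returned unmodified."""
    conn0 = _connectivity_violations(s)
    clash0 = _clash_pairs(s)
    report = {
        "connectivity_before": len(conn0),
        "clashes_before": len(clash0),
        "iterations": 0,
    }
    if not conn0 and not clash0:
        report.update(connectivity_after=0, clashes_after=0)
        return s, report

    out = s.copy()
    movable = _movable_mask(out)
    offsets = np.cumsum([0] + [len(c) for c in out.coords])

    def atom_index(i, name):
        return offsets[i] + out.atom_names[i].index(name)

    movable_flat = np.concatenate(movable)
    for it in range(max_iter):
        changed = False
        # connectivity: move O3' (movable) toward the next residue's P
        for i, _ in _connectivity_violations(out):
            o3 = out.atom_coord(i, "O3'")
            p = out.atom_coord(i + 1, "P")
            v = o3 - p
            norm = np.linalg.norm(v)
            if norm < 1e-9:
                v = np.array([O3P_TARGET, 0.0, 0.0])
                norm = O3P_TARGET
            new = p + v / norm * O3P_TARGET
            out.coords[i][out.atom_names[i].index("O3'")] = new
            changed = True
        # steric overlaps: push movable atoms apart (damped)
        coords = out.all_coords()
        for a, b in _clash_pairs(out):
            d = coords[b] - coords[a]
            dist = np.linalg.norm(d)
            if dist < 1e-9:
                d, dist = np.array([1.0, 0.0, 0.0]), 1.0
            push = 0.4 * (CLASH_DIST - dist) * d / dist
            if movable_flat[a]:
                coords[a] -= push
                changed = True
            if movable_flat[b]:
                coords[b] += push
                changed = True
        pos = 0
        for i, c in enumerate(out.coords):
            out.coords[i] = coords[pos : pos + len(c)]
            pos += len(c)
        report["iterations"] = it + 1
        if not changed:
            break
        if not _connectivity_violations(out) and not _clash_pairs(out):
            break
    report["connectivity_after"] = len(_connectivity_violations(out))
    report["clashes_after"] = len(_clash_pairs(out))
    return out, report


# ---------------------------------------------------------------------------
# external refinement hook


def refinement_steps(n_atoms: int, k: float = REFINEMENT_K) -> int:
    """Step count k * N_atoms / 20 for the external minimizer."""
    return int(round(k * n_atoms / 20.0))


def refinement_hook(
    s: FullAtomStructure, command: list = None, k: float = REFINEMENT_K
) -> FullAtomStructure:
    """Hand the structure to an external all-atom minimizer.

    ``command`` is a argv template; occurrences of ``{in}``, ``{out}``
    and ``{steps}`` are substituted.  Without a configured command (or on
    any failure) the input is returned unchanged with a warning.
    """
    steps = refinement_steps(s.n_atoms, k)
    if not command:
        warnings.warn(
            "no external minimizer configured; returning structure unchanged "
            f"(would run {steps} steps)"
        )
        return s
    from .io import read_pdb, write_pdb

    try:
        with tempfile.TemporaryDirectory() as tmp:
            fin, fout = f"{tmp}/in.pdb", f"{tmp}/out.pdb"
            write_pdb(s, fin)
            argv = [
                str(a).replace("{in}", fin).replace("{out}", fout).replace(
                    "{steps}", str(steps)
                )
                for a in command
            ]
            subprocess.run(argv, check=True, capture_output=True)
            return read_pdb(fout)
    except Exception as exc:  # noqa: BLE001 - best-effort hook
        warnings.warn(f"external refinement failed ({exc}); returning input")
        return s
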