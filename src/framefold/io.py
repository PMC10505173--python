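"""File formats: FASTA, PDB, probability matrices, and the keyed-array
restraint archive (HDF5).

PDB handling is deliberately narrow: single model, single chain,
standard RNA residues (A/U/G/C plus the N placeholder), no insertion
codes.  The restraint archive stores the six geometry probability
tensors under ``geometry/<term>`` and end-to-end frame ensembles under
``e2e/rotations`` (K x L x 3 x 3) and ``e2e/translations`` (K x L x 3),
with metadata (L, bin-spec hash, format version) as root attributes.
"""

from __future__ import annotations

import hashlib
import json
import warnings

import numpy as np

from .features import GEOMETRY_TERMS
from .geometry import (
    BeadStructure,
    FrameSet,
    FullAtomStructure,
    GLYCOSIDIC_N,
    NucleotideSequence,
)
from .potentials import E2ePrediction, GeometryRestraints

ARCHIVE_VERSION = 1


class InputFormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> NucleotideSequence:
    """Read a single-record FASTA.  T is silently mapped to U; other
    unknown letters become 'N' with a warning."""
    seqs = []
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if current is not None and not current:
                    raise InputFormatError("empty FASTA record")
                if current is not None and seqs:
                    raise InputFormatError("expected a single-record FASTA")
                current = []
                seqs.append(current)
            else:
                if current is None:
                    current = []
                    seqs.append(current)
                current.append(line)
    if not seqs or not seqs[0]:
        raise InputFormatError("empty FASTA file")
    if len(seqs) > 1:
        raise InputFormatError("expected a single-record FASTA")
    raw = "".join(seqs[0]).upper().replace("T", "U")
    cleaned = []
    unknown = set()
    for ch in raw:
        if ch in "AUGCN":
            cleaned.append(ch)
        else:
            unknown.add(ch)
            cleaned.append("N")
    if unknown:
        warnings.warn(f"unknown letters {sorted(unknown)} mapped to 'N'")
    if not cleaned:
        raise InputFormatError("FASTA record contains no sequence")
    return NucleotideSequence(cleaned)


# ---------------------------------------------------------------------------
# PDB

_ELEMENT_OF = {"P": "P", "O": "O", "N": "N", "C": "C"}


def _element(atom_name: str) -> str:
    return _ELEMENT_OF.get(atom_name.strip()[0], "C")


def write_pdb(s: FullAtomStructure, path) -> None:
    """Write a single-chain PDB file (1-based residue numbering)."""
    with open(path, "w") as fh:
        serial = 1
        for i, (base, names, xyz) in enumerate(
            zip(s.res_names, s.atom_names, s.coords)
        ):
            for name, c in zip(names, xyz):
                pad = name if len(name) >= 4 else f" {name:<3s}"
                fh.write(
                    f"ATOM  {serial:5d} {pad:<4s} {base:>3s} {s.chain_id}"
                    f"{i + 1:4d}    {c[0]:8.3f}{c[1]:8.3f}{c[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {_element(name):>2s}\n"
                )
                serial += 1
        fh.write("END\n")


def write_bead_pdb(beads: BeadStructure, sequence, path) -> None:
    """Write a 3-bead model as a PDB with P, C4' and the glycosidic N."""
    res_names, atom_names, coords = [], [], []
    for i, base in enumerate(sequence):
        res_names.append(base if base != "N" else "U")
        atom_names.append(["P", "C4'", GLYCOSIDIC_N[base]])
        coords.append(beads.coords[i])
    write_pdb(FullAtomStructure(res_names, atom_names, coords), path)


def read_pdb(path) -> FullAtomStructure:
    """Read a single-model, single-chain RNA PDB file."""
    import gemmi

    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise InputFormatError(f"cannot parse PDB: {exc}") from exc
    if len(st) == 0:
        raise InputFormatError("PDB contains no model")
    model = st[0]
    chains = [ch for ch in model if len(ch) > 0]
    if not chains:
        raise InputFormatError("PDB contains no chain")
    if len(chains) > 1:
        raise InputFormatError("multi-chain PDB files are not supported")
    chain = chains[0]
    res_names, atom_names, coords = [], [], []
    for res in chain:
        if res.seqid.icode not in (" ", "", "\x00"):
            raise InputFormatError(
                f"insertion codes are not supported (residue {res.seqid.num})"
            )
        name = res.name.strip()
        if name not in ("A", "U", "G", "C", "N"):
            raise InputFormatError(f"unsupported residue {name!r}")
        res_names.append(name)
        atom_names.append([a.name for a in res])
        coords.append(np.array([[a.pos.x, a.pos.y, a.pos.z] for a in res]))
    if not res_names:
        raise InputFormatError("no residues found")
    return FullAtomStructure(res_names, atom_names, coords, chain.name or "A")


def beads_from_pdb(path):
    """Read a PDB and extract the 3-bead structure (missing bead atoms
    mask the residue with a warning)."""
    full = read_pdb(path)
    beads = full.to_beads()
    if not beads.mask.all():
        bad = np.nonzero(~beads.mask)[0]
        warnings.warn(f"residues missing bead atoms, masked: {list(bad)}")
    return beads, full


# ---------------------------------------------------------------------------
# probability matrices


def read_probability_matrix(path, L: int = None) -> np.ndarray:
    """Whitespace-delimited L x L pair-probability matrix."""
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise InputFormatError("probability matrix must be square")
    if L is not None and m.shape[0] != L:
        raise InputFormatError(f"matrix is {m.shape[0]} x {m.shape[0]}, expected L={L}")
    return m


# ---------------------------------------------------------------------------
# restraint archive


def bin_spec_hash() -> str:
    """Hash of the geometry bin specification compiled into the code."""
    payload = json.dumps(
        {
            name: [spec.kind, spec.n_content, spec.lo, spec.hi,
                   spec.gate_atom, spec.gate_max]
            for name, spec in GEOMETRY_TERMS.items()
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def save_restraints(
    path, geometry: GeometryRestraints = None, e2e: E2ePrediction = None
) -> None:
    import h5py

    if geometry is None and e2e is None:
        raise ValueError("nothing to save")
    with h5py.File(path, "w") as fh:
        L = geometry.length if geometry is not None else e2e.length
        fh.attrs["L"] = L
        fh.attrs["version"] = ARCHIVE_VERSION
        fh.attrs["bin_spec"] = bin_spec_hash()
        if geometry is not None:
            grp = fh.create_group("geometry")
            for name in GEOMETRY_TERMS:
                grp.create_dataset(name, data=geometry[name])
        if e2e is not None:
            grp = fh.create_group("e2e")
            grp.create_dataset(
                "rotations", data=np.stack([fs.rotations for fs in e2e])
            )
            grp.create_dataset(
                "translations", data=np.stack([fs.translations for fs in e2e])
            )


def load_restraints(path):
    """Returns ``(GeometryRestraints or None, E2ePrediction or None)``."""
    import h5py

    with h5py.File(path, "r") as fh:
        L = int(fh.attrs["L"])
        if fh.attrs.get("bin_spec") != bin_spec_hash():
            raise InputFormatError(
                "restraint archive was written with a different bin specification"
            )
        geometry = None
        e2e = None
        if "geometry" in fh:
            tensors = {name: fh["geometry"][name][()] for name in GEOMETRY_TERMS}
            geometry = GeometryRestraints(tensors)
            if geometry.length != L:
                raise InputFormatError("metadata L does not match tensor shapes")
        if "e2e" in fh:
            rots = fh["e2e"]["rotations"][()]
            trans = fh["e2e"]["translations"][()]
            if rots.shape[1] != L:
                raise InputFormatError("metadata L does not match frame shapes")
            e2e = E2ePrediction(
                [FrameSet(r, t) for r, t in zip(rots, trans)]
            )
    return geometry, e2e
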