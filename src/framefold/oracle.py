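"""Synthetic restraint oracles: reference structures, noisy frame
predictions, and sharpened geometry probability tensors.

These stand in for trained networks when exercising the folding stage:
a reference structure with known secondary structure is built from the
ideal-helix generator, its measured geometry is smeared into per-pair
probability tensors (a Gaussian over bin index around the true bin,
controlled by a temperature), and its true frames are replicated K times
with seeded rotation/translation noise to emulate an ensemble of
end-to-end predictions.  At temperature -> 0 the restraints become
one-hot on the true bins, making the reference the minimum of the
geometry potential; at temperature -> infinity they become uniform and
carry no information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .features import GEOMETRY_TERMS, MASKED_LABEL, geometry_labels
from .geometry import (
    BeadStructure,
    FrameSet,
    FullAtomStructure,
    NucleotideSequence,
    build_ideal_helix,
    frames_from_structure,
)
from .metrics import superpose_rmsd
from .potentials import E2ePrediction, GeometryRestraints
from .secondary import SecondaryStructure


@dataclass
class OracleConfig:
    temperature: float = 0.5  # Gaussian width over bin index
    rot_noise_deg: float = 5.0  # rotation noise std per replica
    trans_noise: float = 1.0  # A translation noise std per replica
    n_replicas: int = 6  # K end-to-end replicas
    #: coordinate noise (A, superposed P-RMSD) applied to the reference
    #: before measuring geometry labels -- emulates the error of a trained
    #: geometry network; 0 gives restraints centered exactly on the truth
    geometry_noise: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.temperature < 0 or self.geometry_noise < 0:
            raise ValueError("temperature and noise levels must be non-negative")
        if self.n_replicas < 1:
            raise ValueError("need at least one replica")


# ---------------------------------------------------------------------------
# reference structures


def _complement(seq: str) -> str:
    return seq.translate(str.maketrans("AUGC", "UACG"))


def make_reference(kind: str, stem: int = 6, loop: int = 4, seed: int = 0):
    """A deterministic reference structure with known secondary structure.

    Kinds: ``duplex`` (stem base pairs as one self-complementary chain),
    ``hairpin`` (stem + loop), ``two-helix-junction`` (two tandem
    hairpins separated by a 2-nt linker).  Returns ``(BeadStructure,
    SecondaryStructure, FullAtomStructure, NucleotideSequence)``.
    """
    if stem < 1 or loop < 0:
        raise ValueError("invalid lengths")
    motif = "GACU"
    s1 = "".join(motif[i % 4] for i in range(stem))
    if kind == "duplex":
        seq = s1 + _complement(s1)[::-1]
        pairs = [(i, 2 * stem - 1 - i) for i in range(stem)]
    elif kind == "hairpin":
        seq = s1 + "A" * loop + _complement(s1)[::-1]
        pairs = [(i, 2 * stem + loop - 1 - i) for i in range(stem)]
    elif kind == "two-helix-junction":
        unit = s1 + "A" * loop + _complement(s1)[::-1]
        n = len(unit)
        seq = unit + "AA" + unit
        pairs = [(i, 2 * stem + loop - 1 - i) for i in range(stem)]
        pairs += [(n + 2 + i, n + 2 + 2 * stem + loop - 1 - i) for i in range(stem)]
    else:
        raise ValueError(f"unknown reference kind {kind!r}")
    sequence = NucleotideSequence(seq)
    ss = SecondaryStructure(set(pairs), length=len(seq))
    full, beads = build_ideal_helix(sequence, pairs)
    return beads, ss, full, sequence


# ---------------------------------------------------------------------------
# geometry oracle


def _smear(labels: np.ndarray, spec, temperature: float) -> np.ndarray:
    """Per-pair probability tensor: Gaussian over content-bin index
    centered on the true bin (circular for dihedrals), all mass on the
    extra bin(s) when the label is an extra bin."""
    L = labels.shape[0]
    n = spec.n_total
    out = np.zeros((L, L, n))
    if spec.kind == "distance":
        content = np.arange(1, 1 + spec.n_content)
        extra = [0, n - 1]
    else:
        content = np.arange(spec.n_content)
        extra = [spec.n_content]
    lab = labels.copy()
    masked = lab == MASKED_LABEL
    lab[masked] = content[0]
    is_extra = np.isin(lab, extra)
    if temperature <= 1e-9:
        probs = (content[None, None, :] == lab[:, :, None]).astype(float)
    else:
        d = np.abs(content[None, None, :] - lab[:, :, None]).astype(float)
        if spec.kind == "dihedral":
            d = np.minimum(d, spec.n_content - d)  # circular
        probs = np.exp(-0.5 * (d / temperature) ** 2)
    norm = probs.sum(axis=-1, keepdims=True)
    probs = probs / np.where(norm > 0, norm, 1.0)  # extra-bin rows overwritten below
    out[:, :, content] = probs
    for e in extra:
        sel = labels == e
        out[sel] = 0.0
        out[sel, e] = 1.0
    out[masked] = 1.0 / n  # uniform placeholder on masked entries
    return out


def oracle_geometry(ref: BeadStructure, cfg: OracleConfig) -> GeometryRestraints:
    """Geometry restraints centered on the reference's bins (optionally
    measured on a noise-perturbed copy, emulating an imperfect network),
    spread by the temperature."""
    if cfg.geometry_noise > 0:
        ref = perturb(ref, cfg.geometry_noise, seed=cfg.seed + 7919)
    labels = geometry_labels(ref)
    tensors = {
        name: _smear(labels[name], spec, cfg.temperature)
        for name, spec in GEOMETRY_TERMS.items()
    }
    return GeometryRestraints(tensors)


# ---------------------------------------------------------------------------
# end-to-end oracle


def oracle_e2e(
    ref: BeadStructure, cfg: OracleConfig, sequence
) -> E2ePrediction:
    """K replicas of the reference's true frames with seeded noise:
    rotation angle ~ N(0, rot_noise) about a random axis and translation
    ~ N(0, trans_noise) per residue."""
    true = frames_from_structure(ref, sequence)
    rng = np.random.default_rng(cfg.seed)
    L = len(true)
    replicas = []
    for _ in range(cfg.n_replicas):
        if cfg.rot_noise_deg > 0:
            axes = rng.normal(size=(L, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            angles = np.deg2rad(rng.normal(scale=cfg.rot_noise_deg, size=L))
            Rn = Rotation.from_rotvec(axes * angles[:, None]).as_matrix()
        else:
            Rn = np.broadcast_to(np.eye(3), (L, 3, 3))
        dt = (
            rng.normal(scale=cfg.trans_noise, size=(L, 3))
            if cfg.trans_noise > 0
            else np.zeros((L, 3))
        )
        replicas.append(
            FrameSet(np.einsum("lmn,lnk->lmk", Rn, true.rotations),
                     true.translations + dt)
        )
    return E2ePrediction(replicas)


# ---------------------------------------------------------------------------
# perturbation


def perturb(ref: BeadStructure, rmsd_target: float, seed: int = 0) -> BeadStructure:
    """Gaussian coordinate noise rescaled so the realized superposed
    P-RMSD to the reference is within 10% of the target."""
    if rmsd_target < 0:
        raise ValueError("rmsd target must be non-negative")
    if rmsd_target == 0:
        return BeadStructure(ref.coords.copy(), ref.mask.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=ref.coords.shape)
    scale = rmsd_target
    out = ref
    for _ in range(8):
        cand = BeadStructure(ref.coords + scale * noise, ref.mask.copy())
        realized, _ = superpose_rmsd(cand, ref, atom="P")
        if abs(realized - rmsd_target) <= 0.1 * rmsd_target:
            return cand
        scale *= rmsd_target / max(realized, 1e-9)
        out = cand
    return out
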