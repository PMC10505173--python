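"""Training objectives: FAPE, inter-N distance cross-entropy, geometry
cross-entropy, and their weighted combination.

The end-to-end objective is ``1.5 * L_FAPE + 0.6 * L_dist``.  FAPE (frame
aligned point error) compares two structures expressed in every residue's
local frame,

    mean_{i,j} min(d_cut, sqrt(||T_i^-1(x_j) - T_i'^-1(x_j')||^2 + eps)),

with ``i`` running over the L residue frames and ``j`` over all 3L bead
atoms realized through their own residues' frames.  The double local-frame
expression cancels any global rigid motion but not reflection, which is
what makes the loss sensitive to chirality.  ``d_cut`` = 30 A and
``eps`` = 1e-3 A^2 under the square root; with a perfect prediction every
term equals sqrt(eps).

The geometry objective is a weighted cross-entropy over the six binned
geometry terms, weight 1.0 for distances and 0.5 for dihedrals.

All losses are differentiable; the ``*_t`` variants operate on autodiff
tensors and power both toy training and gradient checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, astensor, einsum
from .features import E2E_DIST_SPEC, GEOMETRY_TERMS, MASKED_LABEL, discretize_distances
from .geometry import FrameSet, derive_templates

_PCLIP = 1e-12


@dataclass
class LossConfig:
    fape_weight: float = 1.5
    dist_weight: float = 0.6
    d_cut: float = 30.0  # A
    epsilon: float = 1e-3  # A^2, inside the FAPE square root
    geo_dist_weight: float = 1.0
    geo_dih_weight: float = 0.5
    fape_reduce: str = "mean"  # "mean" | "sum"

    def __post_init__(self):
        if min(
            self.fape_weight, self.dist_weight, self.d_cut, self.epsilon,
            self.geo_dist_weight, self.geo_dih_weight,
        ) <= 0:
            raise ValueError("all loss-config values must be positive")
        if self.fape_reduce not in ("mean", "sum"):
            raise ValueError("fape_reduce must be 'mean' or 'sum'")


def residue_templates(sequence) -> np.ndarray:
    """L x 3 x 3 local bead-template coordinates, one per residue."""
    templates = derive_templates()
    return np.stack([templates[b].local_coords for b in sequence])


# ---------------------------------------------------------------------------
# FAPE


def fape_t(
    pred_R, pred_t, true_R, true_t, local: np.ndarray, cfg: LossConfig
) -> Tensor:
    """FAPE on autodiff tensors.

    ``pred_R``/``true_R`` are (L, 3, 3), ``pred_t``/``true_t`` (L, 3);
    ``local`` is the (L, 3, 3) per-residue bead template.
    """
    pred_R, pred_t = astensor(pred_R), astensor(pred_t)
    true_R, true_t = astensor(true_R), astensor(true_t)
    L = local.shape[0]

    def local_views(R, t):
        # atom positions through their own frames, then into every frame i
        x = einsum("lmn,lan->lam", R, Tensor(local)) + t.reshape(L, 1, 3)
        xf = x.reshape(L * 3, 3)
        diff = xf.reshape(1, L * 3, 3) - t.reshape(L, 1, 3)
        return einsum("imn,ijm->ijn", R, diff)

    d2 = ((local_views(pred_R, pred_t) - local_views(true_R, true_t)) ** 2).sum(
        axis=-1
    )
    e = (d2 + cfg.epsilon).sqrt().clip(hi=cfg.d_cut)
    return e.mean() if cfg.fape_reduce == "mean" else e.sum()


def fape(
    pred_frames: FrameSet,
    true_frames: FrameSet,
    templates: np.ndarray,
    cfg: LossConfig = None,
) -> float:
    """Frame aligned point error between two frame sets.

    ``templates`` is the (L, 3, 3) per-residue local bead template (see
    :func:`residue_templates`).  Invariant to global rigid motion of
    either frame set; sensitive to reflection.
    """
    cfg = cfg or LossConfig()
    if len(pred_frames) != len(true_frames):
        raise ValueError("frame sets must have equal length")
    templates = np.asarray(templates, dtype=float)
    if templates.shape != (len(pred_frames), 3, 3):
        raise ValueError("templates must be L x 3 x 3")
    return fape_t(
        pred_frames.rotations, pred_frames.translations,
        true_frames.rotations, true_frames.translations,
        templates, cfg,
    ).item()


# ---------------------------------------------------------------------------
# cross-entropies


def _ce_sum_t(probs: Tensor, labels: np.ndarray, n_bins: int) -> Tensor:
    """-sum log p at the labeled bin over unmasked ordered pairs."""
    valid = labels != MASKED_LABEL
    ii, jj = np.nonzero(valid)
    picked = probs[ii, jj, labels[ii, jj]]
    return -(picked.clip(lo=_PCLIP).log().sum())


def _check_normalized(p: np.ndarray, n_bins: int, what: str) -> None:
    p = np.asarray(p, dtype=float)
    if p.ndim != 3 or p.shape[2] != n_bins:
        raise ValueError(f"{what} must be L x L x {n_bins}")
    sums = p.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-5:
        raise ValueError(f"{what} probability slices must sum to 1 (within 1e-5)")


def distance_ce_t(pred_probs, labels: np.ndarray) -> Tensor:
    return _ce_sum_t(astensor(pred_probs), labels, E2E_DIST_SPEC.n_total)


def distance_ce(pred_probs: np.ndarray, true_N_distances: np.ndarray) -> float:
    """Cross-entropy of the 38-bin inter-N distance prediction against
    the binned true distances (diagonal masked)."""
    _check_normalized(pred_probs, E2E_DIST_SPEC.n_total, "distance prediction")
    labels = discretize_distances(true_N_distances, E2E_DIST_SPEC)
    np.fill_diagonal(labels, MASKED_LABEL)
    return distance_ce_t(pred_probs, labels).item()


def geometry_ce_t(pred: dict, labels: dict, cfg: LossConfig) -> Tensor:
    total = None
    for name, spec in GEOMETRY_TERMS.items():
        w = cfg.geo_dist_weight if spec.kind == "distance" else cfg.geo_dih_weight
        ce = _ce_sum_t(astensor(pred[name]), labels[name], spec.n_total)
        term = w * ce
        total = term if total is None else total + term
    return total


def geometry_ce(pred: dict, labels: dict, cfg: LossConfig = None) -> float:
    """Weighted cross-entropy over the six geometry terms (distance
    terms weight 1.0, dihedral terms 0.5)."""
    cfg = cfg or LossConfig()
    missing = set(GEOMETRY_TERMS) - set(pred)
    if missing:
        raise ValueError(f"missing geometry term(s): {sorted(missing)}")
    for name, spec in GEOMETRY_TERMS.items():
        _check_normalized(pred[name], spec.n_total, name)
    return geometry_ce_t(pred, labels, cfg).item()


def e2e_total(fape_value: float, dist_ce_value: float, cfg: LossConfig = None) -> float:
    """The end-to-end objective: 1.5 * FAPE + 0.6 * distance CE."""
    cfg = cfg or LossConfig()
    return cfg.fape_weight * fape_value + cfg.dist_weight * dist_ce_value
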