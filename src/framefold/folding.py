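"""Multi-start L-BFGS minimization of the hybrid energy in frame space.

The conformation is parameterized per residue by an exponential-map
(axis-angle) rotation vector plus a translation -- six unconstrained
numbers per residue -- so the optimizer works on a flat vector while
every evaluation reconstitutes proper rotation matrices.  Each start
(by default the end-to-end predictions themselves) is optimized
independently with the same energy; the lowest-energy final conformation
wins, with ties broken by the lowest trajectory index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ._autodiff import Tensor, stack
from .geometry import BeadStructure, FrameSet, NucleotideSequence, build_ideal_helix
from .losses import residue_templates
from .potentials import (
    E2ePrediction,
    GeometryRestraints,
    PotentialConfig,
    build_geometry_potential,
    energy_hybrid_t,
)


@dataclass
class FoldingConfig:
    max_iter: int = 400
    tol: float = 1e-6  # energy-change convergence tolerance
    n_starts: int = None  # default: one per e2e prediction
    seed: int = 0
    history: int = 10  # L-BFGS memory
    potential: PotentialConfig = field(default_factory=PotentialConfig)

    def __post_init__(self):
        if self.max_iter <= 0 or (self.n_starts is not None and self.n_starts <= 0):
            raise ValueError("iteration and start counts must be positive")
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class Trajectory:
    frames: FrameSet
    beads: BeadStructure
    energies: list
    converged: bool
    failed: bool = False
    message: str = ""


@dataclass
class FoldingResult:
    trajectories: list
    selected_index: int

    @property
    def selected(self) -> Trajectory:
        return self.trajectories[self.selected_index]

    @property
    def selected_energy(self) -> float:
        return self.selected.energies[-1]


# ---------------------------------------------------------------------------
# parameterization


def frames_to_params(frames: FrameSet) -> np.ndarray:
    """Flatten a frame set into per-residue (rotvec, translation)."""
    w = Rotation.from_matrix(frames.rotations).as_rotvec()
    return np.concatenate([w, frames.translations], axis=1).ravel()


def params_to_frames(x: np.ndarray, L: int) -> FrameSet:
    p = x.reshape(L, 6)
    R = Rotation.from_rotvec(p[:, :3]).as_matrix()
    return FrameSet(R, p[:, 3:].copy())


def _rotvec_to_matrix_t(w: Tensor) -> Tensor:
    """Batched Rodrigues formula on autodiff tensors: (L, 3) -> (L, 3, 3)."""
    L = w.shape[0]
    theta = ((w * w).sum(axis=-1) + 1e-16).sqrt()  # (L,)
    k = w / theta.reshape(L, 1)
    kx, ky, kz = k[:, 0], k[:, 1], k[:, 2]
    zero = Tensor(np.zeros(L))
    K = stack(
        [
            stack([zero, -kz, ky], axis=-1),
            stack([kz, zero, -kx], axis=-1),
            stack([-ky, kx, zero], axis=-1),
        ],
        axis=-2,
    )  # (L, 3, 3)
    s = theta.sin().reshape(L, 1, 1)
    c = theta.cos().reshape(L, 1, 1)
    eye = Tensor(np.broadcast_to(np.eye(3), (L, 3, 3)).copy())
    return eye + s * K + (1.0 - c) * (K @ K)


# ---------------------------------------------------------------------------
# optimization


def optimize_conformation(
    start: FrameSet,
    energy_t,
    local: np.ndarray,
    cfg: FoldingConfig = None,
) -> Trajectory:
    """L-BFGS trajectory from one start.

    ``energy_t(R, t)`` must return a scalar autodiff Tensor given the
    (L, 3, 3) rotations and (L, 3) translations as Tensors.  Returns the
    final frames, bead coordinates, and the accepted-step energy trace.
    A NaN energy aborts the trajectory (marked failed).
    """
    cfg = cfg or FoldingConfig()
    L = len(start)
    x0 = frames_to_params(start)
    trace: list[float] = []

    def fun(x):
        xt = Tensor(x.reshape(L, 6), requires_grad=True)
        R = _rotvec_to_matrix_t(xt[:, :3])
        t = xt[:, 3:]
        e = energy_t(R, t)
        xt.zero_grad()
        e.backward()
        return float(e.data), xt.grad.ravel().copy()

    e0, _ = fun(x0)
    if not np.isfinite(e0):
        return Trajectory(start, None, [e0], False, True, "non-finite start energy")
    trace.append(e0)

    def cb(xk):
        ek, _ = fun(xk)
        trace.append(min(ek, trace[-1]) if np.isfinite(ek) else ek)

    try:
        res = minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={
                "maxiter": cfg.max_iter,
                "maxcor": cfg.history,
                "ftol": cfg.tol,
                "gtol": 1e-8,
            },
        )
    except (FloatingPointError, ValueError) as exc:  # pragma: no cover
        return Trajectory(start, None, trace, False, True, str(exc))
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        return Trajectory(start, None, trace, False, True, "NaN energy during optimization")
    frames = params_to_frames(res.x, L)
    if trace[-1] > res.fun:
        trace.append(float(res.fun))
    return Trajectory(frames, _frames_to_beads(frames, local), trace, bool(res.success))


def _frames_to_beads(frames: FrameSet, local: np.ndarray) -> BeadStructure:
    coords = np.einsum("lmn,lan->lam", frames.rotations, local) + frames.translations[:, None, :]
    return BeadStructure(coords)


# ---------------------------------------------------------------------------
# the folding driver


def _perturbed_helix_starts(sequence, n: int, rng: np.random.Generator):
    """Fallback starts when no end-to-end predictions exist: an ideal
    A-form chain with seeded Gaussian frame noise."""
    from .geometry import frames_from_structure

    L = len(sequence)
    _, beads = build_ideal_helix(sequence, [])
    base = frames_from_structure(beads, sequence)
    starts = []
    for _ in range(n):
        w = rng.normal(scale=0.15, size=(L, 3))
        dt = rng.normal(scale=1.0, size=(L, 3))
        R = Rotation.from_rotvec(w).as_matrix() @ base.rotations
        starts.append(FrameSet(R, base.translations + dt))
    return starts


def fold(
    sequence,
    e2e_pred: E2ePrediction = None,
    geo: GeometryRestraints = None,
    cfg: FoldingConfig = None,
    starts: list = None,
) -> FoldingResult:
    """Fold a sequence against the hybrid potential.

    One L-BFGS trajectory is run per start (the e2e predictions by
    default; random-perturbed ideal-helix frames when only geometry
    restraints are given); the conformation with the lowest final energy
    is selected, ties broken by the lowest trajectory index.
    """
    cfg = cfg or FoldingConfig()
    if e2e_pred is None and geo is None:
        raise ValueError("need e2e predictions and/or geometry restraints")
    sequence = (
        sequence
        if isinstance(sequence, NucleotideSequence)
        else NucleotideSequence(sequence)
    )
    local = residue_templates(sequence)
    potentials = build_geometry_potential(geo, cfg=cfg.potential) if geo else None

    def energy_t(R, t):
        return energy_hybrid_t(R, t, local, e2e_pred, potentials, cfg.potential)

    if starts is None:
        if e2e_pred is not None:
            starts = list(e2e_pred)
            if cfg.n_starts is not None:
                starts = starts[: cfg.n_starts]
        else:
            rng = np.random.default_rng(cfg.seed)
            starts = _perturbed_helix_starts(
                sequence, cfg.n_starts or 6, rng
            )

    trajectories = [
        optimize_conformation(s, energy_t, local, cfg) for s in starts
    ]
    ok = [k for k, tr in enumerate(trajectories) if not tr.failed]
    if not ok:
        raise RuntimeError("all folding trajectories failed")
    selected = min(ok, key=lambda k: (trajectories[k].energies[-1], k))
    return FoldingResult(trajectories, selected)
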