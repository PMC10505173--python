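"""Embedding layer, RNA transformer blocks, and the IPA-based structure
module, at configurable scale.

The architecture follows the Evoformer-style design: a sequence
representation ``s`` (L x D_s) and a pair representation ``z``
(L x L x D_z) are produced by an embedding layer (linear projections of
the one-hot sequence and the secondary-structure pair features, plus 1-D
index and 2-D relative-position encodings) and refined by a stack of
transformer blocks.  Each block applies, residually: sequence row-wise
gated self-attention with pair bias, a sequence transition, an outer
product mean, two triangle multiplicative updates (outgoing and
incoming edges), two triangle self-attention blocks, and a pair
transition.

The structure module consumes (s, z) and iteratively updates per-residue
rigid frames with invariant point attention (IPA): attention logits mix
scalar queries/keys, a pair bias, and distances between query/key points
expressed in global coordinates through the current frames, which makes
the update equivariant under global rigid motions.  Frames start from
identity ("black hole") initialization and compose a quaternion-derived
rotation plus translation update each iteration.

In end-to-end mode the network returns frames (realizing bead
coordinates through the nucleotide templates) and a 38-bin inter-N
distance map; in geometry mode it returns the six binned geometry
probability tensors.  A recycling loop feeds the previous cycle's
representations (and, in end-to-end mode, the binned bead-distance map
of the previous structure) back into the next cycle.

Everything runs on the numpy autodiff engine at float64; the default
hyperparameters mirror the full-scale design (48 blocks, 64-d
representations, IPA (8, 16, 4, 6), 5 structure iterations, 3 recycles)
while the toy preset is small enough to train on one CPU in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor, concatenate, einsum, stack
from .features import E2E_DIST_SPEC, GEOMETRY_TERMS, discretize_distances
from .geometry import FrameSet
from .losses import LossConfig, distance_ce_t, fape_t, geometry_ce_t


@dataclass
class NetworkConfig:
    n_blocks: int = 48
    d_seq: int = 64
    d_pair: int = 64
    seq_heads: int = 8
    seq_head_dim: int = 8
    transition_factor: int = 2  # 64 -> 128 -> 64
    opm_dim: int = 12
    tri_mult_dim: int = 32
    tri_attn_heads: int = 4
    tri_attn_head_dim: int = 8
    struct_d_seq: int = 128
    struct_d_pair: int = 64
    ipa_heads: int = 8
    ipa_dim: int = 16
    ipa_query_points: int = 4
    ipa_point_values: int = 6
    struct_iterations: int = 5
    n_recycles: int = 3
    max_relpos: int = 32
    max_len: int = 512
    mode: str = "e2e"  # "e2e" | "geometry"
    #: use two starting-node triangle attention blocks instead of the
    #: default starting + ending node pair
    double_starting_node: bool = False
    #: detach rotation gradients between structure iterations (a
    #: stability device for large-scale training; full gradient flow
    #: trains much faster at toy scale)
    stop_rotation_gradients: bool = False

    def __post_init__(self):
        for name in (
            "n_blocks", "d_seq", "d_pair", "seq_heads", "seq_head_dim",
            "opm_dim", "tri_mult_dim", "tri_attn_heads", "tri_attn_head_dim",
            "struct_d_seq", "struct_d_pair", "ipa_heads", "ipa_dim",
            "ipa_query_points", "ipa_point_values", "struct_iterations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @staticmethod
    def toy(mode: str = "e2e", **overrides) -> "NetworkConfig":
        """A preset small enough for CPU property tests and overfits."""
        cfg = NetworkConfig(
            n_blocks=2, d_seq=16, d_pair=16, seq_heads=4, seq_head_dim=4,
            opm_dim=4, tri_mult_dim=8, tri_attn_heads=2, tri_attn_head_dim=4,
            struct_d_seq=16, struct_d_pair=16, ipa_heads=4, ipa_dim=8,
            ipa_query_points=2, ipa_point_values=3, struct_iterations=3,
            n_recycles=1, mode=mode,
        )
        return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# parameter primitives


class Linear:
    def __init__(self, d_in, d_out, rng, init="lecun", bias=True):
        if init == "zero":
            W = np.zeros((d_in, d_out))
        else:
            W = rng.normal(scale=1.0 / np.sqrt(d_in), size=(d_in, d_out))
        self.W = Tensor(W, requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.W
        return y + self.b if self.b is not None else y

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class LayerNorm:
    def __init__(self, d):
        self.gamma = Tensor(np.ones(d), requires_grad=True)
        self.beta = Tensor(np.zeros(d), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta)

    def params(self):
        return [self.gamma, self.beta]


def _params_of(*modules):
    out = []
    for m in modules:
        out.extend(m.params())
    return out


# ---------------------------------------------------------------------------
# embedding


class Embedding:
    """Sequence/pair feature embedding with positional encodings."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.cfg = cfg
        self.seq_proj = Linear(5, cfg.d_seq, rng)
        self.left = Linear(5, cfg.d_pair, rng)
        self.right = Linear(5, cfg.d_pair, rng)
        self.pair_proj = Linear(4, cfg.d_pair, rng)
        self.pos_table = Tensor(
            rng.normal(scale=0.02, size=(cfg.max_len, cfg.d_seq)),
            requires_grad=True,
        )
        self.relpos_proj = Linear(2 * cfg.max_relpos + 1, cfg.d_pair, rng)

    def __call__(self, seq_feat: np.ndarray, pair_feat: np.ndarray):
        cfg = self.cfg
        L = seq_feat.shape[0]
        if seq_feat.shape != (L, 5) or pair_feat.shape != (L, L, 4):
            raise ValueError("feature shapes must be (L, 5) and (L, L, 4)")
        sf = Tensor(seq_feat)
        s = self.seq_proj(sf) + self.pos_table[np.minimum(np.arange(L), cfg.max_len - 1)]
        z = (
            self.left(sf).reshape(L, 1, cfg.d_pair)
            + self.right(sf).reshape(1, L, cfg.d_pair)
            + self.pair_proj(Tensor(pair_feat))
        )
        rel = np.clip(
            np.arange(L)[None, :] - np.arange(L)[:, None],
            -cfg.max_relpos,
            cfg.max_relpos,
        ) + cfg.max_relpos
        onehot = np.eye(2 * cfg.max_relpos + 1)[rel]
        z = z + self.relpos_proj(Tensor(onehot))
        return s, z

    def params(self):
        return _params_of(
            self.seq_proj, self.left, self.right, self.pair_proj, self.relpos_proj
        ) + [self.pos_table]


# ---------------------------------------------------------------------------
# transformer sub-blocks (all residual; output projections zero-initialized
# so a fresh block is the identity)


class SeqAttention:
    """Row-wise gated self-attention with pair bias."""

    def __init__(self, cfg: NetworkConfig, rng):
        H, dh = cfg.seq_heads, cfg.seq_head_dim
        self.H, self.dh = H, dh
        self.ln = LayerNorm(cfg.d_seq)
        self.ln_z = LayerNorm(cfg.d_pair)
        self.q = Linear(cfg.d_seq, H * dh, rng, bias=False)
        self.k = Linear(cfg.d_seq, H * dh, rng, bias=False)
        self.v = Linear(cfg.d_seq, H * dh, rng, bias=False)
        self.bias = Linear(cfg.d_pair, H, rng, bias=False)
        self.gate = Linear(cfg.d_seq, H * dh, rng, init="zero")
        self.out = Linear(H * dh, cfg.d_seq, rng, init="zero")

    def __call__(self, s: Tensor, z: Tensor) -> Tensor:
        L = s.shape[0]
        H, dh = self.H, self.dh
        x = self.ln(s)
        q = self.q(x).reshape(L, H, dh)
        k = self.k(x).reshape(L, H, dh)
        v = self.v(x).reshape(L, H, dh)
        b = self.bias(self.ln_z(z)).transpose(2, 0, 1)  # (H, L, L)
        logits = einsum("ihc,jhc->hij", q, k) * (1.0 / np.sqrt(dh)) + b
        a = logits.softmax(axis=-1)
        o = einsum("hij,jhc->ihc", a, v)
        g = self.gate(x).reshape(L, H, dh).sigmoid()
        return self.out((g * o).reshape(L, H * dh))

    def params(self):
        return _params_of(
            self.ln, self.ln_z, self.q, self.k, self.v, self.bias, self.gate, self.out
        )


class Transition:
    """Two-layer feed-forward expansion (d -> f*d -> d)."""

    def __init__(self, d, factor, rng):
        self.ln = LayerNorm(d)
        self.l1 = Linear(d, factor * d, rng)
        self.l2 = Linear(factor * d, d, rng, init="zero")

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(self.ln(x)).relu())

    def params(self):
        return _params_of(self.ln, self.l1, self.l2)


class OuterProductMean:
    def __init__(self, cfg: NetworkConfig, rng):
        self.ln = LayerNorm(cfg.d_seq)
        self.a = Linear(cfg.d_seq, cfg.opm_dim, rng)
        self.b = Linear(cfg.d_seq, cfg.opm_dim, rng)
        self.out = Linear(cfg.opm_dim**2, cfg.d_pair, rng, init="zero")
        self.d = cfg.opm_dim

    def __call__(self, s: Tensor) -> Tensor:
        L = s.shape[0]
        x = self.ln(s)
        a, b = self.a(x), self.b(x)
        outer = einsum("ic,jd->ijcd", a, b).reshape(L, L, self.d**2)
        return self.out(outer)

    def params(self):
        return _params_of(self.ln, self.a, self.b, self.out)


class TriangleMultiplication:
    def __init__(self, cfg: NetworkConfig, rng, outgoing: bool):
        c = cfg.tri_mult_dim
        self.outgoing = outgoing
        self.ln = LayerNorm(cfg.d_pair)
        self.a = Linear(cfg.d_pair, c, rng)
        self.a_gate = Linear(cfg.d_pair, c, rng, init="zero")
        self.b = Linear(cfg.d_pair, c, rng)
        self.b_gate = Linear(cfg.d_pair, c, rng, init="zero")
        self.ln_out = LayerNorm(c)
        self.out = Linear(c, cfg.d_pair, rng, init="zero")
        self.out_gate = Linear(cfg.d_pair, cfg.d_pair, rng, init="zero")

    def __call__(self, z: Tensor) -> Tensor:
        x = self.ln(z)
        a = self.a(x) * self.a_gate(x).sigmoid()
        b = self.b(x) * self.b_gate(x).sigmoid()
        if self.outgoing:
            prod = einsum("ikc,jkc->ijc", a, b)
        else:
            prod = einsum("kic,kjc->ijc", a, b)
        return self.out(self.ln_out(prod)) * self.out_gate(x).sigmoid()

    def params(self):
        return _params_of(
            self.ln, self.a, self.a_gate, self.b, self.b_gate,
            self.ln_out, self.out, self.out_gate,
        )


class TriangleAttention:
    """Triangle self-attention around the starting (or ending) node."""

    def __init__(self, cfg: NetworkConfig, rng, starting: bool):
        H, dh = cfg.tri_attn_heads, cfg.tri_attn_head_dim
        self.H, self.dh, self.starting = H, dh, starting
        self.ln = LayerNorm(cfg.d_pair)
        self.q = Linear(cfg.d_pair, H * dh, rng, bias=False)
        self.k = Linear(cfg.d_pair, H * dh, rng, bias=False)
        self.v = Linear(cfg.d_pair, H * dh, rng, bias=False)
        self.bias = Linear(cfg.d_pair, H, rng, bias=False)
        self.gate = Linear(cfg.d_pair, H * dh, rng, init="zero")
        self.out = Linear(H * dh, cfg.d_pair, rng, init="zero")

    def __call__(self, z: Tensor) -> Tensor:
        L = z.shape[0]
        H, dh = self.H, self.dh
        x = self.ln(z) if self.starting else self.ln(z).transpose(1, 0, 2)
        q = self.q(x).reshape(L, L, H, dh)
        k = self.k(x).reshape(L, L, H, dh)
        v = self.v(x).reshape(L, L, H, dh)
        b = self.bias(x).transpose(2, 0, 1)  # (H, j, k) bias for edge jk
        logits = einsum("ijhc,ikhc->hijk", q, k) * (1.0 / np.sqrt(dh))
        logits = logits + b.reshape(H, 1, L, L)
        a = logits.softmax(axis=-1)
        o = einsum("hijk,ikhc->ijhc", a, v)
        g = self.gate(x).reshape(L, L, H, dh).sigmoid()
        o = self.out((g * o).reshape(L, L, H * dh))
        return o if self.starting else o.transpose(1, 0, 2)

    def params(self):
        return _params_of(
            self.ln, self.q, self.k, self.v, self.bias, self.gate, self.out
        )


class TransformerBlock:
    """One residual RNA transformer block."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.attn = SeqAttention(cfg, rng)
        self.seq_trans = Transition(cfg.d_seq, cfg.transition_factor, rng)
        self.opm = OuterProductMean(cfg, rng)
        self.tri_out = TriangleMultiplication(cfg, rng, outgoing=True)
        self.tri_in = TriangleMultiplication(cfg, rng, outgoing=False)
        self.tri_attn_1 = TriangleAttention(cfg, rng, starting=True)
        self.tri_attn_2 = TriangleAttention(
            cfg, rng, starting=cfg.double_starting_node
        )
        self.pair_trans = Transition(cfg.d_pair, cfg.transition_factor, rng)

    def __call__(self, s: Tensor, z: Tensor):
        s = s + self.attn(s, z)
        s = s + self.seq_trans(s)
        z = z + self.opm(s)
        z = z + self.tri_out(z)
        z = z + self.tri_in(z)
        z = z + self.tri_attn_1(z)
        z = z + self.tri_attn_2(z)
        z = z + self.pair_trans(z)
        return s, z

    def params(self):
        return _params_of(
            self.attn, self.seq_trans, self.opm, self.tri_out, self.tri_in,
            self.tri_attn_1, self.tri_attn_2, self.pair_trans,
        )


# ---------------------------------------------------------------------------
# frames on tensors


def quat_update_to_rot(bcd: Tensor) -> Tensor:
    """Rotation matrices from unnormalized quaternions (1, b, c, d)."""
    L = bcd.shape[0]
    b, c, d = bcd[:, 0], bcd[:, 1], bcd[:, 2]
    one = Tensor(np.ones(L))
    n = one + b * b + c * c + d * d
    a = one
    rows = [
        [
            (a * a + b * b - c * c - d * d) / n,
            2 * (b * c - a * d) / n,
            2 * (b * d + a * c) / n,
        ],
        [
            2 * (b * c + a * d) / n,
            (a * a - b * b + c * c - d * d) / n,
            2 * (c * d - a * b) / n,
        ],
        [
            2 * (b * d - a * c) / n,
            2 * (c * d + a * b) / n,
            (a * a - b * b - c * c + d * d) / n,
        ],
    ]
    return stack([stack(r, axis=-1) for r in rows], axis=-2)


# ---------------------------------------------------------------------------
# invariant point attention


class InvariantPointAttention:
    def __init__(self, cfg: NetworkConfig, rng):
        H, c = cfg.ipa_heads, cfg.ipa_dim
        Pq, Pv = cfg.ipa_query_points, cfg.ipa_point_values
        ds, dz = cfg.struct_d_seq, cfg.struct_d_pair
        self.H, self.c, self.Pq, self.Pv, self.dz = H, c, Pq, Pv, dz
        self.q = Linear(ds, H * c, rng, bias=False)
        self.k = Linear(ds, H * c, rng, bias=False)
        self.v = Linear(ds, H * c, rng, bias=False)
        self.q_pts = Linear(ds, H * Pq * 3, rng, bias=False)
        self.k_pts = Linear(ds, H * Pq * 3, rng, bias=False)
        self.v_pts = Linear(ds, H * Pv * 3, rng, bias=False)
        self.bias = Linear(dz, H, rng, bias=False)
        self.gamma_raw = Tensor(np.full(H, 0.541324854612918), requires_grad=True)
        self.out = Linear(H * (c + Pv * 4 + dz), ds, rng, init="zero")

    def __call__(self, s: Tensor, z: Tensor, R: Tensor, t: Tensor) -> Tensor:
        L = s.shape[0]
        H, c, Pq, Pv = self.H, self.c, self.Pq, self.Pv
        q = self.q(s).reshape(L, H, c)
        k = self.k(s).reshape(L, H, c)
        v = self.v(s).reshape(L, H, c)
        qp = self.q_pts(s).reshape(L, H * Pq, 3)
        kp = self.k_pts(s).reshape(L, H * Pq, 3)
        vp = self.v_pts(s).reshape(L, H * Pv, 3)
        # local points to global through the current frames
        qp_g = einsum("lmn,lpn->lpm", R, qp) + t.reshape(L, 1, 3)
        kp_g = einsum("lmn,lpn->lpm", R, kp) + t.reshape(L, 1, 3)
        vp_g = einsum("lmn,lpn->lpm", R, vp) + t.reshape(L, 1, 3)
        b = self.bias(z).transpose(2, 0, 1)  # (H, L, L)
        wL = np.sqrt(1.0 / 3.0)
        wC = np.sqrt(2.0 / (9.0 * Pq))
        gamma = self.gamma_raw.softplus()  # (H,)
        diff = qp_g.reshape(L, 1, H, Pq, 3) - kp_g.reshape(1, L, H, Pq, 3)
        d2 = (diff * diff).sum(axis=-1).sum(axis=-1)  # (L, L, H)
        logits = (
            wL * (einsum("ihc,jhc->hij", q, k) * (1.0 / np.sqrt(c)) + b)
            - (wL * wC / 2.0) * (gamma.reshape(1, 1, H) * d2).transpose(2, 0, 1)
        )
        a = logits.softmax(axis=-1)  # (H, i, j)
        o_scalar = einsum("hij,jhc->ihc", a, v).reshape(L, H * c)
        # attention-weighted global points, one set per head
        vp_gh = vp_g.reshape(L, H, Pv, 3)
        o_pth = einsum("hij,jhpm->ihpm", a, vp_gh)  # (L, H, Pv, 3) global
        # back to the local frame of residue i
        rel = o_pth - t.reshape(L, 1, 1, 3)
        o_local = einsum("lmn,lhpm->lhpn", R, rel)  # R^T applied
        o_norm = ((o_local * o_local).sum(axis=-1) + 1e-8).sqrt()
        o_pair = einsum("hij,ijd->ihd", a, z).reshape(L, H * self.dz)
        feats = concatenate(
            [
                o_scalar,
                o_local.reshape(L, H * Pv * 3),
                o_norm.reshape(L, H * Pv),
                o_pair,
            ],
            axis=-1,
        )
        return self.out(feats)

    def params(self):
        return _params_of(
            self.q, self.k, self.v, self.q_pts, self.k_pts, self.v_pts,
            self.bias, self.out,
        ) + [self.gamma_raw]


class StructureModule:
    """Iterative IPA frame refinement from identity initialization."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.cfg = cfg
        self.s_proj = Linear(cfg.d_seq, cfg.struct_d_seq, rng)
        self.z_proj = Linear(cfg.d_pair, cfg.struct_d_pair, rng)
        self.ln_s = LayerNorm(cfg.struct_d_seq)
        self.ipa = InvariantPointAttention(cfg, rng)
        self.ln1 = LayerNorm(cfg.struct_d_seq)
        self.trans = Transition(cfg.struct_d_seq, 2, rng)
        self.ln2 = LayerNorm(cfg.struct_d_seq)
        self.update = Linear(cfg.struct_d_seq, 6, rng, init="zero")

    def forward_t(self, s: Tensor, z: Tensor, R0=None, t0=None, stop_rot=None):
        cfg = self.cfg
        if stop_rot is None:
            stop_rot = cfg.stop_rotation_gradients
        L = s.shape[0]
        sr = self.ln_s(self.s_proj(s))
        zr = self.z_proj(z)
        R = Tensor(np.broadcast_to(np.eye(3), (L, 3, 3)).copy()) if R0 is None else R0
        t = Tensor(np.zeros((L, 3))) if t0 is None else t0
        for it in range(cfg.struct_iterations):
            sr = self.ln1(sr + self.ipa(sr, zr, R, t))
            sr = self.ln2(sr + self.trans(sr))
            upd = self.update(sr)
            R_upd = quat_update_to_rot(upd[:, :3])
            t_upd = upd[:, 3:]
            t = einsum("lmn,ln->lm", R, t_upd) + t
            R = R @ R_upd
            if stop_rot and it < cfg.struct_iterations - 1:
                R = R.stop_gradient()
        return R, t

    def params(self):
        return _params_of(
            self.s_proj, self.z_proj, self.ln_s, self.ipa, self.ln1,
            self.trans, self.ln2, self.update,
        )


def structure_module(s, z, module: StructureModule, initial_frames: FrameSet = None):
    """Run a structure module on representations, returning a FrameSet."""
    R0 = t0 = None
    if initial_frames is not None:
        R0 = Tensor(initial_frames.rotations)
        t0 = Tensor(initial_frames.translations)
    R, t = module.forward_t(
        s if isinstance(s, Tensor) else Tensor(s),
        z if isinstance(z, Tensor) else Tensor(z),
        R0,
        t0,
    )
    # renormalize against accumulated float error before validation
    from .geometry import proper_orthogonalize

    rots = np.stack([proper_orthogonalize(m) for m in R.data])
    return FrameSet(rots, t.data.copy())


# ---------------------------------------------------------------------------
# heads and the full model


class PairHead:
    """Symmetrized per-pair softmax head."""

    def __init__(self, d_pair, n_bins, rng):
        self.proj = Linear(d_pair, n_bins, rng)

    def __call__(self, z: Tensor) -> Tensor:
        logits = self.proj(z)
        logits = logits + logits.transpose(1, 0, 2)
        return logits.softmax(axis=-1)

    def params(self):
        return self.proj.params()


class Model:
    """End-to-end or geometry network with recycling."""

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.cfg = cfg
        self.embed = Embedding(cfg, rng)
        self.blocks = [TransformerBlock(cfg, rng) for _ in range(cfg.n_blocks)]
        self.recycle_ln_s = LayerNorm(cfg.d_seq)
        self.recycle_ln_z = LayerNorm(cfg.d_pair)
        if cfg.mode == "e2e":
            self.structure = StructureModule(cfg, rng)
            self.dist_head = PairHead(cfg.d_pair, E2E_DIST_SPEC.n_total, rng)
            self.recycle_dist = Linear(E2E_DIST_SPEC.n_total, cfg.d_pair, rng, init="zero")
        elif cfg.mode == "geometry":
            self.geo_heads = {
                name: PairHead(cfg.d_pair, spec.n_total, rng)
                for name, spec in GEOMETRY_TERMS.items()
            }
        else:
            raise ValueError("mode must be 'e2e' or 'geometry'")

    def params(self):
        out = self.embed.params()
        for blk in self.blocks:
            out += blk.params()
        out += self.recycle_ln_s.params() + self.recycle_ln_z.params()
        if self.cfg.mode == "e2e":
            out += self.structure.params() + self.dist_head.params()
            out += self.recycle_dist.params()
        else:
            for h in self.geo_heads.values():
                out += h.params()
        return out

    # -- forward -----------------------------------------------------------
    def trunk(self, seq_feat, pair_feat, recycled=None):
        s, z = self.embed(seq_feat, pair_feat)
        if recycled is not None:
            s_prev, z_prev, beads_prev = recycled
            s = s + self.recycle_ln_s(Tensor(s_prev))
            z = z + self.recycle_ln_z(Tensor(z_prev))
            if self.cfg.mode == "e2e" and beads_prev is not None:
                d = np.linalg.norm(
                    beads_prev[:, None, 2] - beads_prev[None, :, 2], axis=-1
                )
                labels = discretize_distances(d, E2E_DIST_SPEC)
                onehot = np.eye(E2E_DIST_SPEC.n_total)[labels]
                z = z + self.recycle_dist(Tensor(onehot))
        for blk in self.blocks:
            s, z = blk(s, z)
        return s, z

    def forward_t(self, seq_feat, pair_feat, recycled=None):
        """One cycle; returns mode-dependent tensors plus (s, z)."""
        s, z = self.trunk(seq_feat, pair_feat, recycled)
        if self.cfg.mode == "e2e":
            R, t = self.structure.forward_t(s, z)
            probs = self.dist_head(z)
            return (R, t, probs), (s, z)
        probs = {name: h(z) for name, h in self.geo_heads.items()}
        return probs, (s, z)


def forward_with_recycling(
    model: Model, seq_feat, pair_feat, n_recycles: int = None, local=None
):
    """Run the model with recycling (previous representations and, in
    end-to-end mode, the previous structure's bead-distance map).

    In e2e mode returns ``(FrameSet, dist_probs, bead_coords)``; in
    geometry mode a dict of the six probability tensors.
    """
    cfg = model.cfg
    n_recycles = cfg.n_recycles if n_recycles is None else n_recycles
    recycled = None
    out = None
    for cycle in range(max(1, n_recycles)):
        out, (s, z) = model.forward_t(seq_feat, pair_feat, recycled)
        if cfg.mode == "e2e":
            R, t, probs = out
            beads = None
            if local is not None:
                beads = (
                    np.einsum("lmn,lan->lam", R.data, local) + t.data[:, None, :]
                )
            recycled = (s.data.copy(), z.data.copy(), beads)
        else:
            recycled = (s.data.copy(), z.data.copy(), None)
    if cfg.mode == "e2e":
        R, t, probs = out
        from .geometry import proper_orthogonalize

        rots = np.stack([proper_orthogonalize(m) for m in R.data])
        frames = FrameSet(rots, t.data.copy())
        beads = None
        if local is not None:
            beads = np.einsum("lmn,lan->lam", rots, local) + t.data[:, None, :]
        return frames, probs.data.copy(), beads
    return {k: v.data.copy() for k, v in out.items()}


# ---------------------------------------------------------------------------
# toy training


class Adam:
    def __init__(self, params, lr=1e-3, b1=0.9, b2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            p.data -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class DivergenceError(RuntimeError):
    def __init__(self, step):
        super().__init__(f"training diverged (NaN loss) at step {step}")
        self.step = step


def train_toy(
    model: Model,
    seq_feat: np.ndarray,
    pair_feat: np.ndarray,
    target,
    steps: int,
    seed: int = 0,
    lr: float = 1e-3,
    loss_cfg: LossConfig = None,
):
    """Overfit a toy model on one RNA (Adam, initial learning rate 1e-3).

    ``target`` is a dict with keys depending on the mode: for e2e,
    ``frames`` (FrameSet), ``local`` (L x 3 x 3 templates) and
    ``dist_labels``; for geometry, ``labels`` (the six bin-index maps).
    Returns ``(loss_trace, model)``; the trace has ``steps + 1`` entries
    (the leading entry is the pre-training loss).  Deterministic given
    the model's seed; raises :class:`DivergenceError` on NaN loss.
    """
    cfg = model.cfg
    loss_cfg = loss_cfg or LossConfig()
    opt = Adam(model.params(), lr=lr)

    def compute_loss():
        if cfg.mode == "e2e":
            (R, t, probs), _ = model.forward_t(seq_feat, pair_feat)
            f = fape_t(
                R, t,
                target["frames"].rotations, target["frames"].translations,
                target["local"], loss_cfg,
            )
            ce = distance_ce_t(probs, target["dist_labels"])
            return loss_cfg.fape_weight * f + loss_cfg.dist_weight * ce
        probs, _ = model.forward_t(seq_feat, pair_feat)
        return geometry_ce_t(probs, target["labels"], loss_cfg)

    trace = []
    loss = compute_loss()
    trace.append(loss.item())
    for step in range(steps):
        if not np.isfinite(trace[-1]):
            raise DivergenceError(step)
        opt.zero_grad()
        loss.backward()
        opt.step()
        loss = compute_loss()
        trace.append(loss.item())
    if not np.isfinite(trace[-1]):
        raise DivergenceError(steps)
    return trace, model
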