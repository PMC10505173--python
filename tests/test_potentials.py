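"""Spline geometry potentials and the FAPE-form end-to-end potential."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from framefold._autodiff import Tensor
from framefold.features import GEOMETRY_TERMS
from framefold.geometry import BeadStructure, FrameSet
from framefold.oracle import OracleConfig, make_reference, oracle_geometry, perturb
from framefold.potentials import (
    E2ePrediction,
    GeometryRestraints,
    PotentialConfig,
    build_geometry_potential,
    energy_e2e,
    energy_geo,
    energy_geo_t,
    energy_hybrid,
    energy_hybrid_t,
)

SQRT_EPS = np.sqrt(1e-3)


def _uniform_restraints(L):
    tensors = {}
    for name, spec in GEOMETRY_TERMS.items():
        tensors[name] = np.full((L, L, spec.n_total), 1.0 / spec.n_total)
    return GeometryRestraints(tensors)


def _one_hot_restraints(labels):
    from framefold.features import MASKED_LABEL

    tensors = {}
    for name, spec in GEOMETRY_TERMS.items():
        lab = labels[name]
        L = lab.shape[0]
        floor = 1e-9
        p = np.full((L, L, spec.n_total), floor)
        for i in range(L):
            for j in range(L):
                b = lab[i, j] if lab[i, j] != MASKED_LABEL else 0
                p[i, j, b] = 1.0
        tensors[name] = p / p.sum(axis=-1, keepdims=True)
    return GeometryRestraints(tensors)


# ---------------------------------------------------------------------------
# spline construction


def test_uniform_restraints_give_flat_zero_potential(hairpin):
    L = len(hairpin["beads"])
    pots = build_geometry_potential(_uniform_restraints(L))
    for name, pot in pots.items():
        spec = pot.spec
        xs = np.linspace(spec.lo, spec.hi, 101)
        vals = pot.evaluate(xs, 0, 1)
        assert np.abs(vals).max() < 1e-9, name


def test_one_hot_minimum_near_true_bin_center(hairpin):
    """Dense scan: the spline minimum sits within half a bin width of
    the hot bin's center, for every term."""
    from framefold.features import geometry_labels

    labels = geometry_labels(hairpin["beads"])
    pots = build_geometry_potential(_one_hot_restraints(labels))
    for name, pot in pots.items():
        spec = pot.spec
        centers = spec.content_centers()
        for (i, j) in [(0, 5), (2, 9)]:
            lab = labels[name][i, j]
            if spec.kind == "distance":
                if not (1 <= lab <= spec.n_content):
                    continue
                center = centers[lab - 1]
            else:
                if lab >= spec.n_content:
                    continue
                center = centers[lab]
            xs = np.linspace(spec.lo, spec.hi, 10000)
            vals = pot.evaluate(xs, i, j)
            assert abs(xs[np.argmin(vals)] - center) <= spec.bin_width / 2 + 1e-6, name


def test_dihedral_spline_periodic_boundary(hairpin, rng):
    from framefold.features import geometry_labels

    labels = geometry_labels(hairpin["beads"])
    pots = build_geometry_potential(_one_hot_restraints(labels))
    for name in ("dih_PCCP", "dih_CNNC", "dih_PNNP"):
        v_lo = pots[name].evaluate(float(-np.pi), 0, 7)
        v_hi = pots[name].evaluate(float(np.pi), 0, 7)
        assert v_lo == pytest.approx(v_hi, abs=1e-9)


def test_spline_reproduces_knot_values(hairpin, rng):
    """Spline curves pass exactly through their knot values."""
    from framefold.features import geometry_labels

    labels = geometry_labels(hairpin["beads"])
    r = oracle_geometry(hairpin["beads"], OracleConfig(temperature=1.5))
    cfg = PotentialConfig()
    pots = build_geometry_potential(r, cfg=cfg)
    for name, pot in pots.items():
        spec = pot.spec
        P = r[name]
        i, j = 1, 8
        if spec.kind == "distance":
            ref = P[i, j, spec.n_content]
            expected = -np.log((P[i, j, 1 : 1 + spec.n_content] + cfg.eps) / (ref + cfg.eps))
            knots = spec.content_centers()
        else:
            ref = P[i, j, spec.n_content - 1]
            expected = -0.5 * np.log(
                (P[i, j, : spec.n_content] + cfg.eps) / (ref + cfg.eps)
            )
            knots = spec.content_centers()
        vals = pot.evaluate(knots, i, j)
        assert np.allclose(vals, expected, atol=1e-9), name


def test_unnormalized_dihedral_config_switch(hairpin):
    r = oracle_geometry(hairpin["beads"], OracleConfig(temperature=1.0))
    cfg = PotentialConfig(normalize_dihedral=False)
    pots = build_geometry_potential(r, cfg=cfg)
    P = r["dih_PCCP"]
    i, j = 0, 9
    knots = GEOMETRY_TERMS["dih_PCCP"].content_centers()
    vals = pots["dih_PCCP"].evaluate(knots, i, j)
    assert np.allclose(vals, -0.5 * np.log(P[i, j, :36] + cfg.eps), atol=1e-9)


# ---------------------------------------------------------------------------
# geometry energy


def test_energy_geo_uniform_is_zero(hairpin):
    L = len(hairpin["beads"])
    pots = build_geometry_potential(_uniform_restraints(L))
    assert abs(energy_geo(hairpin["beads"], pots)) < 1e-6 * len(GEOMETRY_TERMS)


def test_energy_geo_reference_below_perturbed(hairpin):
    """With sharp oracle restraints the reference conformation scores
    below displaced copies, across seeds."""
    beads = hairpin["beads"]
    r = oracle_geometry(beads, OracleConfig(temperature=0.3, geometry_noise=0.0))
    pots = build_geometry_potential(r)
    e_ref = energy_geo(beads, pots)
    for seed in range(20):
        e_pert = energy_geo(perturb(beads, 5.0, seed), pots)
        assert e_ref < e_pert


def test_energy_geo_gradient_finite_difference(rng):
    """Autodiff gradient of the geometry energy on a 4-residue toy
    matches central differences."""
    beads, _, _, seq = make_reference("hairpin", stem=2, loop=0)
    coords = beads.coords[:4] + rng.normal(scale=0.2, size=(4, 3, 3))
    r = oracle_geometry(BeadStructure(beads.coords[:4]), OracleConfig(temperature=1.0))
    pots = build_geometry_potential(r)
    x = Tensor(coords.copy(), requires_grad=True)
    e = energy_geo_t(x, pots)
    e.backward()
    g = x.grad.copy()
    eps = 1e-5
    for idx in [(0, 0, 1), (2, 1, 0), (3, 2, 2)]:
        c = coords.copy()
        c[idx] += eps
        hi = energy_geo_t(Tensor(c), pots).item()
        c[idx] -= 2 * eps
        lo = energy_geo_t(Tensor(c), pots).item()
        num = (hi - lo) / (2 * eps)
        assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


# ---------------------------------------------------------------------------
# e2e energy


def test_energy_e2e_at_single_prediction(hairpin):
    f = hairpin["frames"]
    pred = E2ePrediction([f])
    L = len(f)
    expect = SQRT_EPS * L * 3 * L  # every term saturates at sqrt(eps)
    assert energy_e2e(f, pred, hairpin["local"]) == pytest.approx(expect, rel=1e-9)


def test_energy_e2e_replica_linearity(hairpin):
    f = hairpin["frames"]
    rs = np.random.RandomState(3)
    other = FrameSet(
        Rotation.random(len(f), random_state=rs).as_matrix(),
        rs.normal(scale=5, size=(len(f), 3)),
    )
    e1 = energy_e2e(other, E2ePrediction([f]), hairpin["local"])
    e6 = energy_e2e(other, E2ePrediction([f] * 6), hairpin["local"])
    assert e6 == pytest.approx(6 * e1, rel=1e-12)


def test_energy_e2e_two_residue_brute_force():
    local = np.stack([np.eye(3) - 1 / 3, (np.eye(3) - 1 / 3) * 2.0])
    rs = np.random.RandomState(17)
    conf = FrameSet(Rotation.random(2, random_state=rs).as_matrix(), rs.normal(size=(2, 3)))
    pred = FrameSet(Rotation.random(2, random_state=rs).as_matrix(), rs.normal(size=(2, 3)))
    cfg = PotentialConfig()
    total = 0.0
    atoms_c = [conf[j].apply(local[j]) for j in range(2)]
    atoms_p = [pred[j].apply(local[j]) for j in range(2)]
    for i in range(2):
        for j in range(2):
            for a in range(3):
                dc = conf[i].invert().apply(atoms_c[j][a][None])[0]
                dp = pred[i].invert().apply(atoms_p[j][a][None])[0]
                total += min(cfg.d_cut, np.sqrt(((dc - dp) ** 2).sum() + cfg.fape_epsilon))
    assert energy_e2e(conf, E2ePrediction([pred]), local) == pytest.approx(total, abs=1e-10)


def test_energy_e2e_joint_rigid_invariance(hairpin):
    """Moving conformation AND predictions by the same rigid motion
    leaves the energy unchanged."""
    from framefold.geometry import RigidFrame

    f = hairpin["frames"]
    rs = np.random.RandomState(23)
    conf = FrameSet(
        Rotation.random(len(f), random_state=rs).as_matrix(),
        rs.normal(scale=4, size=(len(f), 3)),
    )
    pred = E2ePrediction([f])
    base = energy_e2e(conf, pred, hairpin["local"])
    g = RigidFrame(Rotation.random(random_state=rs).as_matrix(), rs.normal(size=3) * 7)
    moved_pred = E2ePrediction([f.transformed_by(g)])
    assert energy_e2e(conf.transformed_by(g), moved_pred, hairpin["local"]) == pytest.approx(
        base, abs=1e-8
    )


# ---------------------------------------------------------------------------
# hybrid


def test_hybrid_modes(hairpin):
    beads = hairpin["beads"]
    f = hairpin["frames"]
    local = hairpin["local"]
    pred = E2ePrediction([f])
    r = oracle_geometry(beads, OracleConfig(temperature=0.5))
    pots = build_geometry_potential(r)
    e_geo = energy_hybrid(f, local, None, pots)
    e_e2e = energy_hybrid(f, local, pred, None)
    e_both = energy_hybrid(f, local, pred, pots)
    assert e_geo == pytest.approx(energy_geo(beads, pots), abs=1e-6)
    assert e_e2e == pytest.approx(energy_e2e(f, pred, local), abs=1e-12)
    assert e_both == pytest.approx(e_geo + e_e2e, abs=1e-6)
    with pytest.raises(ValueError):
        energy_hybrid(f, local, None, None)


def test_energy_descends_along_negative_gradient(hairpin):
    """A small step along the negative gradient lowers the hybrid
    energy from a random perturbed conformation."""
    from framefold.folding import _rotvec_to_matrix_t, frames_to_params

    beads = hairpin["beads"]
    local = hairpin["local"]
    r = oracle_geometry(beads, OracleConfig(temperature=0.5))
    pots = build_geometry_potential(r)
    pred = E2ePrediction([hairpin["frames"]])
    start = perturb(beads, 3.0, seed=5)
    from framefold.geometry import frames_from_structure

    frames = frames_from_structure(start, hairpin["sequence"])
    x0 = frames_to_params(frames).reshape(len(frames), 6)

    def energy(x):
        xt = Tensor(x, requires_grad=True)
        R = _rotvec_to_matrix_t(xt[:, :3])
        e = energy_hybrid_t(R, xt[:, 3:], local, pred, pots)
        xt.zero_grad()
        e.backward()
        return e.item(), xt.grad

    e0, g = energy(x0)
    for step in (1e-5, 1e-4):
        e1, _ = energy(x0 - step * g)
        assert e1 < e0


def test_restraint_validation():
    bad = {name: np.full((3, 3, spec.n_total), 0.5) for name, spec in GEOMETRY_TERMS.items()}
    with pytest.raises(ValueError):
        GeometryRestraints(bad)
    with pytest.raises(ValueError):
        E2ePrediction([])
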