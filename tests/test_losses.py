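"""Training objectives: FAPE, distance cross-entropy, geometry
cross-entropy, and the weighted end-to-end total."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from framefold._autodiff import Tensor, gradcheck
from framefold.features import E2E_DIST_SPEC, GEOMETRY_TERMS, MASKED_LABEL, discretize_distances
from framefold.geometry import FrameSet, RigidFrame, mirror_structure, frames_from_structure
from framefold.losses import (
    LossConfig,
    distance_ce,
    e2e_total,
    fape,
    fape_t,
    geometry_ce,
    residue_templates,
)

SQRT_EPS = np.sqrt(1e-3)


def _rand_frameset(L, seed):
    rs = np.random.RandomState(seed)
    R = Rotation.random(L, random_state=rs).as_matrix()
    return FrameSet(R, rs.normal(scale=8, size=(L, 3)))


def _rand_global(seed):
    rs = np.random.RandomState(seed)
    return RigidFrame(Rotation.random(random_state=rs).as_matrix(), rs.normal(size=3) * 10)


# ---------------------------------------------------------------------------
# FAPE


def test_fape_perfect_prediction_is_sqrt_eps(hairpin):
    f = hairpin["frames"]
    val = fape(f, f, hairpin["local"])
    assert val == pytest.approx(SQRT_EPS, rel=1e-9)


def test_fape_global_rigid_invariance(hairpin):
    f = hairpin["frames"]
    pred = _rand_frameset(len(f), 3)
    base = fape(pred, f, hairpin["local"])
    for seed in (1, 2):
        g = _rand_global(seed)
        assert fape(pred.transformed_by(g), f, hairpin["local"]) == pytest.approx(base, abs=1e-8)
        assert fape(pred, f.transformed_by(g), hairpin["local"]) == pytest.approx(base, abs=1e-8)


def test_fape_two_residue_brute_force():
    """2-residue system: the loss equals the explicitly enumerated
    double sum over 2 frames x 6 atoms."""
    local = np.stack([np.eye(3) - 1 / 3, (np.eye(3) - 1 / 3) * 1.5])
    pred = _rand_frameset(2, 11)
    true = _rand_frameset(2, 12)
    cfg = LossConfig()
    total = 0.0
    atoms_p = [pred[j].apply(local[j]) for j in range(2)]
    atoms_t = [true[j].apply(local[j]) for j in range(2)]
    for i in range(2):
        for j in range(2):
            for a in range(3):
                dp = pred[i].invert().apply(atoms_p[j][a][None])[0]
                dt = true[i].invert().apply(atoms_t[j][a][None])[0]
                total += min(cfg.d_cut, np.sqrt(((dp - dt) ** 2).sum() + cfg.epsilon))
    total /= 2 * 6
    assert fape(pred, true, local) == pytest.approx(total, abs=1e-10)


def test_fape_reflection_sensitivity(hairpin):
    """A mirrored chiral helix scores strictly worse than the original
    (the property credited for handedness recovery)."""
    seq = hairpin["sequence"]
    mirrored = frames_from_structure(mirror_structure(hairpin["beads"]), seq)
    same = fape(hairpin["frames"], hairpin["frames"], hairpin["local"])
    flipped = fape(mirrored, hairpin["frames"], hairpin["local"])
    assert flipped > same + 1.0


def test_fape_clamp_saturation(hairpin):
    """Inflating one inter-frame error beyond d_cut leaves the loss
    unchanged thereafter."""
    f = hairpin["frames"]
    far = FrameSet(f.rotations.copy(), f.translations.copy())
    far.translations[0] += 500.0
    v1 = fape(far, f, hairpin["local"])
    far.translations[0] += 500.0
    v2 = fape(far, f, hairpin["local"])
    assert v1 == pytest.approx(v2, abs=1e-9)


def test_fape_sum_mode_scales_by_terms(hairpin):
    f = hairpin["frames"]
    pred = _rand_frameset(len(f), 5)
    L = len(f)
    mean = fape(pred, f, hairpin["local"], LossConfig(fape_reduce="mean"))
    total = fape(pred, f, hairpin["local"], LossConfig(fape_reduce="sum"))
    assert total == pytest.approx(mean * L * 3 * L, rel=1e-9)


def test_fape_gradient_matches_finite_differences():
    local = np.stack([np.eye(3) - 1 / 3] * 3)
    true = _rand_frameset(3, 21)
    cfg = LossConfig()
    rs = np.random.RandomState(4)
    t0 = Tensor(rs.normal(scale=3, size=(3, 3)), requires_grad=True)

    def f(t):
        R = Tensor(np.broadcast_to(np.eye(3), (3, 3, 3)).copy())
        return fape_t(R, t, true.rotations, true.translations, local, cfg)

    assert gradcheck(f, [t0], rtol=1e-5) == 0.0


def test_fape_length_mismatch(hairpin):
    with pytest.raises(ValueError):
        fape(_rand_frameset(4, 0), hairpin["frames"], hairpin["local"])


# ---------------------------------------------------------------------------
# distance cross-entropy


def _labels_for(dists):
    lab = discretize_distances(dists, E2E_DIST_SPEC)
    np.fill_diagonal(lab, MASKED_LABEL)
    return lab


def test_distance_ce_one_hot_correct(hairpin):
    from framefold.features import pairwise_distances

    d = pairwise_distances(hairpin["beads"], "N")
    lab = _labels_for(d)
    L = d.shape[0]
    probs = np.full((L, L, 38), 1e-12 / 37)
    for i in range(L):
        for j in range(L):
            b = lab[i, j] if lab[i, j] != MASKED_LABEL else 0
            probs[i, j, b] = 1.0 - 1e-12
    assert distance_ce(probs, d) == pytest.approx(0.0, abs=1e-6)


def test_distance_ce_uniform_closed_form():
    d = np.full((5, 5), 10.0)
    np.fill_diagonal(d, 0.0)
    probs = np.full((5, 5, 38), 1 / 38)
    assert distance_ce(probs, d) == pytest.approx(5 * 4 * np.log(38), rel=1e-12)


def test_distance_ce_brute_force(rng):
    L = 3
    d = rng.uniform(3, 45, size=(L, L))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    raw = rng.uniform(0.1, 1.0, size=(L, L, 38))
    probs = raw / raw.sum(axis=-1, keepdims=True)
    lab = _labels_for(d)
    expect = 0.0
    for i in range(L):
        for j in range(L):
            if i == j:
                continue
            expect -= np.log(probs[i, j, lab[i, j]])
    assert distance_ce(probs, d) == pytest.approx(expect, abs=1e-10)


def test_distance_ce_rejects_unnormalized():
    with pytest.raises(ValueError):
        distance_ce(np.full((2, 2, 38), 0.5), np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# geometry cross-entropy


def _random_geometry_pred(L, rng):
    pred = {}
    for name, spec in GEOMETRY_TERMS.items():
        raw = rng.uniform(0.1, 1.0, size=(L, L, spec.n_total))
        pred[name] = raw / raw.sum(axis=-1, keepdims=True)
    return pred


def test_geometry_ce_one_hot_correct(hairpin):
    from framefold.features import geometry_labels

    labels = geometry_labels(hairpin["beads"])
    L = len(hairpin["beads"])
    pred = {}
    for name, spec in GEOMETRY_TERMS.items():
        p = np.full((L, L, spec.n_total), 1e-12)
        lab = labels[name]
        for i in range(L):
            for j in range(L):
                b = lab[i, j] if lab[i, j] != MASKED_LABEL else 0
                p[i, j, b] = 1.0
        pred[name] = p / p.sum(axis=-1, keepdims=True)
    assert geometry_ce(pred, labels) == pytest.approx(0.0, abs=1e-6)


def test_geometry_ce_weights_by_linearity(hairpin, rng):
    """Doubling only the dihedral CE increases the total by 0.5x that
    increase; distance terms carry weight 1.0."""
    from framefold.features import geometry_labels

    labels = geometry_labels(hairpin["beads"])
    L = len(hairpin["beads"])
    pred = _random_geometry_pred(L, rng)
    base = geometry_ce(pred, labels)
    # sharpen all dihedral predictions to exact one-hot: their CE drops to ~0
    dih_ce = 0.0
    for name, spec in GEOMETRY_TERMS.items():
        if spec.kind != "dihedral":
            continue
        lab = labels[name]
        valid = lab != MASKED_LABEL
        ii, jj = np.nonzero(valid)
        dih_ce += -np.log(pred[name][ii, jj, lab[ii, jj]]).sum()
        p = np.full((L, L, spec.n_total), 1e-12)
        p[ii, jj, lab[ii, jj]] = 1.0
        pred[name] = p / p.sum(axis=-1, keepdims=True)
    sharpened = geometry_ce(pred, labels)
    assert base - sharpened == pytest.approx(0.5 * dih_ce, rel=1e-6)


def test_geometry_ce_brute_force(rng):
    L = 3
    coords = rng.normal(scale=6, size=(L, 3, 3))
    from framefold.features import geometry_labels
    from framefold.geometry import BeadStructure

    labels = geometry_labels(BeadStructure(coords))
    pred = _random_geometry_pred(L, rng)
    expect = 0.0
    for name, spec in GEOMETRY_TERMS.items():
        w = 1.0 if spec.kind == "distance" else 0.5
        lab = labels[name]
        for i in range(L):
            for j in range(L):
                if lab[i, j] == MASKED_LABEL:
                    continue
                expect -= w * np.log(pred[name][i, j, lab[i, j]])
    assert geometry_ce(pred, labels) == pytest.approx(expect, abs=1e-10)


def test_geometry_ce_missing_term(hairpin, rng):
    from framefold.features import geometry_labels

    labels = geometry_labels(hairpin["beads"])
    pred = _random_geometry_pred(len(hairpin["beads"]), rng)
    del pred["dih_PNNP"]
    with pytest.raises(ValueError, match="dih_PNNP"):
        geometry_ce(pred, labels)


# ---------------------------------------------------------------------------
# totals


@pytest.mark.parametrize(
    "f,d,expected", [(0.0, 0.0, 0.0), (1.0, 1.0, 2.1), (2.0, 5.0, 6.0)]
)
def test_e2e_total_weights(f, d, expected):
    assert e2e_total(f, d) == pytest.approx(expected, abs=1e-12)


def test_loss_config_validation():
    with pytest.raises(ValueError):
        LossConfig(fape_weight=0.0)
    with pytest.raises(ValueError):
        LossConfig(fape_reduce="median")
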