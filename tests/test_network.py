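"""Siamese network invariants: sharing, pooling oracle, CAM identity."""

from __future__ import annotations

import numpy as np
import pytest

from collascore.network import (
    BackboneConfig,
    ScoreDistribution,
    SiameseCollateralNet,
    average_cams,
    classify,
    classify_whole_brain,
    downsample_mask,
    load_checkpoint,
    masked_gap,
    pad_to_multiple,
    save_checkpoint,
)
from collascore.preprocess import HemispherePair

RNG = np.random.default_rng(9)


def _pair(shape=(8, 8, 8), symmetric=False, seed=0):
    rng = np.random.default_rng(seed)
    aff = rng.uniform(-1, 1, shape).astype(np.float32)
    heal = aff.copy() if symmetric else rng.uniform(-1, 1, shape).astype(np.float32)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[2:6, 2:6, 2:6] = 1
    return HemispherePair(aff, heal, mask, overlap_voxels=1)


# ----------------------------------------------------------------- pooling
def test_pad_to_multiple():
    v = np.ones((5, 6, 7), dtype=np.float32)
    out = pad_to_multiple(v, 4, fill=-1.0)
    assert out.shape == (8, 8, 8)
    assert out[:5, :6, :7].min() == 1.0 and out[5:].max() == -1.0
    same = pad_to_multiple(np.ones((4, 4, 4)), 4)
    assert same.shape == (4, 4, 4)


def test_downsample_mask_any_pooling():
    m = np.zeros((4, 4, 4), dtype=np.uint8)
    m[1, 0, 0] = 1  # single voxel marks its 2x2x2 block
    d = downsample_mask(m, 2)
    assert d.shape == (2, 2, 2)
    assert d[0, 0, 0] and d.sum() == 1


def test_masked_gap_single_voxel_and_constant():
    fmap = RNG.normal(size=(3, 4, 4, 4)).astype(np.float32)
    mask = np.zeros((4, 4, 4), dtype=bool)
    mask[1, 2, 3] = True
    np.testing.assert_allclose(masked_gap(fmap, mask), fmap[:, 1, 2, 3], atol=1e-6)
    const = np.full((2, 4, 4, 4), 3.5, dtype=np.float32)
    full = np.ones((4, 4, 4), dtype=bool)
    np.testing.assert_allclose(masked_gap(const, full), 3.5, atol=1e-6)


def test_masked_gap_matches_bruteforce_loop():
    fmap = RNG.normal(size=(2, 3, 4, 4, 4)).astype(np.float32)
    mask = RNG.random((4, 4, 4)) > 0.5
    got = masked_gap(fmap, mask)
    idx = np.argwhere(mask)
    for n in range(2):
        for c in range(3):
            ref = np.mean([fmap[n, c, i, j, k] for i, j, k in idx])
            assert got[n, c] == pytest.approx(ref, abs=1e-5)


def test_masked_gap_rejects_empty_mask():
    with pytest.raises(ValueError):
        masked_gap(np.zeros((1, 2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


# ---------------------------------------------------------- weight sharing
def test_branches_share_weights(tiny_model):
    """Identical halves must produce identical feature maps (one backbone)."""
    x = RNG.uniform(-1, 1, (8, 8, 8)).astype(np.float32)
    fa = tiny_model.extract_features(x)
    fb = tiny_model.extract_features(x.copy())
    np.testing.assert_array_equal(fa, fb)
    assert fa.shape == (3, 4, 4, 4)  # n_features, half resolution


def test_prediction_valid_distribution(tiny_model):
    dist = classify(_pair(), tiny_model)
    assert isinstance(dist, ScoreDistribution)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
    assert dist.p23 == pytest.approx(dist[2] + dist[3])


def test_antisymmetric_head_on_symmetric_pair(tiny_model):
    """With head weights w_aff = -w_heal, a perfectly symmetric pair yields
    logits equal to the bias (difference of identical pooled features)."""
    f = tiny_model.cfg.n_features
    w = RNG.normal(size=(4, f)).astype(np.float32)
    tiny_model.head.weight.value[:, :f] = w
    tiny_model.head.weight.value[:, f:] = -w
    tiny_model.head.bias.value[...] = [0.3, -0.1, 0.2, 0.0]
    z = tiny_model.forward_logits(_pair(symmetric=True))
    np.testing.assert_allclose(z, [0.3, -0.1, 0.2, 0.0], atol=1e-4)


def test_input_size_guard(tiny_backbone):
    model = SiameseCollateralNet(BackboneConfig(2, (1, 1), full_res_stem=False))
    small = _pair(shape=(3, 8, 8))
    with pytest.raises(ValueError):
        model.forward_logits(small)


# --------------------------------------------------------------------- CAM
def test_cam_masked_mean_equals_logit(tiny_model):
    pair = _pair(seed=4)
    z = tiny_model.forward_logits(pair)
    cam = tiny_model.compute_cam(pair)
    for c in range(4):
        assert cam.masked_mean(c) == pytest.approx(float(z[c]), abs=1e-4)
        assert cam.logits[c] == pytest.approx(float(z[c]), abs=1e-4)


def test_cam_contributions_sum_to_map(tiny_model):
    cam = tiny_model.compute_cam(_pair(seed=5))
    b = tiny_model.head.bias.value.astype(np.float64)[:, None, None, None]
    np.testing.assert_allclose(
        cam.class_maps, cam.affected_contrib + cam.healthy_contrib + b, atol=1e-5
    )


def test_average_cams_is_elementwise_mean(tiny_backbone):
    models = [SiameseCollateralNet(tiny_backbone, seed=s) for s in (1, 2)]
    pair = _pair(seed=6)
    cams = [m.compute_cam(pair) for m in models]
    avg = average_cams(cams)
    np.testing.assert_allclose(
        avg.class_maps, (cams[0].class_maps + cams[1].class_maps) / 2, atol=1e-6
    )
    np.testing.assert_allclose(avg.logits, (cams[0].logits + cams[1].logits) / 2, atol=1e-6)


# ----------------------------------------------------- whole-brain ablation
def test_whole_brain_backbone_same_size_head_differs(tiny_backbone):
    siam = SiameseCollateralNet(tiny_backbone, seed=0)
    whole = SiameseCollateralNet(tiny_backbone, whole_brain=True, seed=0)
    f = tiny_backbone.n_features
    n_back = sum(p.value.size for p in siam.backbone.params())
    assert n_back == sum(p.value.size for p in whole.backbone.params())
    assert siam.head.weight.value.shape == (4, 2 * f)
    assert whole.head.weight.value.shape == (4, f)
    assert siam.n_parameters() - whole.n_parameters() == 4 * f


def test_whole_brain_dispatch(tiny_backbone):
    whole = SiameseCollateralNet(tiny_backbone, whole_brain=True, seed=3)
    vol = RNG.uniform(-1, 1, (12, 8, 8)).astype(np.float32)
    mask = np.zeros(vol.shape, dtype=np.uint8)
    mask[3:9, 2:6, 2:6] = 1
    dist = classify_whole_brain(vol, mask, whole)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        classify(_pair(), whole)
    siam = SiameseCollateralNet(tiny_backbone, seed=3)
    with pytest.raises(ValueError):
        classify_whole_brain(vol, mask, siam)


# ------------------------------------------------------------- checkpoints
def test_checkpoint_round_trip(tiny_model, tmp_path):
    pair = _pair(seed=7)
    before = tiny_model.predict(pair).probs
    path = tmp_path / "model.npz"
    save_checkpoint(tiny_model, path, metadata={"note": "unit"})
    loaded, meta = load_checkpoint(path)
    assert meta == {"note": "unit"}
    assert loaded.cfg == tiny_model.cfg
    np.testing.assert_allclose(loaded.predict(pair).probs, before, atol=1e-7)


def test_backward_matches_finite_difference(tiny_model):
    """End-to-end directional gradient check through GAP + backbone."""
    pair = _pair(seed=8)
    w = np.array([0.7, -0.3, 0.5, -0.9], dtype=np.float32)  # random logit weights

    def loss_at():
        return float((tiny_model.forward_logits(pair) * w).sum())

    tiny_model.forward_logits(pair, keep_cache=True)
    for p in tiny_model.params():
        p.zero_grad()
    tiny_model.backward_from_logits(w)

    eps = 2e-2
    rng = np.random.default_rng(0)
    checked = 0
    for p in tiny_model.params():
        d = rng.normal(size=p.value.shape).astype(np.float32)
        d /= max(np.linalg.norm(d), 1e-12)
        orig = p.value.copy()
        p.value = orig + eps * d
        lp = loss_at()
        p.value = orig - eps * d
        lm = loss_at()
        p.value = orig
        fd = (lp - lm) / (2 * eps)
        an = float((p.grad * d).sum())
        assert an == pytest.approx(fd, rel=5e-2, abs=2e-3)
        checked += 1
    assert checked >= 6  # conv, norms, head weights and biases all covered
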