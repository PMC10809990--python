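"""Loss, schedule, balanced sampling, augmentation and training loop."""

from __future__ import annotations

import numpy as np
import pytest

from collascore.phantom import PhantomSpec, generate_dataset
from collascore.pipeline import reduced_backbone
from collascore.training import (
    AugmentationParams,
    TrainingConfig,
    apply_transform,
    augment,
    balanced_epoch,
    cross_validate,
    hybrid_loss,
    hybrid_loss_grad,
    lr_schedule,
    smooth_labels,
    train_ensemble,
    train_model,
)

RNG = np.random.default_rng(33)


# ------------------------------------------------------------- hybrid loss
def test_hybrid_loss_hand_computed_values():
    p = np.array([0.1, 0.2, 0.3, 0.4])
    # y = 2: BCE = -ln(0.7), CCE = -ln(0.3)
    expected = 0.7 * (-np.log(0.7)) + 0.3 * (-np.log(0.3))
    assert hybrid_loss(p, 2, alpha=0.3) == pytest.approx(expected, abs=1e-9)
    # uniform distribution, y = 3
    u = np.full(4, 0.25)
    assert hybrid_loss(u, 3, alpha=1.0) == pytest.approx(np.log(4), abs=1e-9)
    assert hybrid_loss(u, 3, alpha=0.0) == pytest.approx(np.log(2), abs=1e-9)


def test_hybrid_loss_alpha_zero_depends_only_on_p23():
    """The pure-BCE limit cannot distinguish mass split between classes 2/3."""
    a = np.array([0.1, 0.2, 0.69, 0.01])
    b = np.array([0.1, 0.2, 0.01, 0.69])
    assert hybrid_loss(a, 3, 0.0) == pytest.approx(hybrid_loss(b, 3, 0.0), abs=1e-12)
    assert hybrid_loss(a, 3, 1.0) != pytest.approx(hybrid_loss(b, 3, 1.0), abs=1e-6)


def test_hybrid_loss_is_convex_combination():
    p = np.array([0.05, 0.15, 0.45, 0.35])
    for y in range(4):
        bce, cce = hybrid_loss(p, y, 0.0), hybrid_loss(p, y, 1.0)
        mix = hybrid_loss(p, y, 0.3)
        assert mix == pytest.approx(0.7 * bce + 0.3 * cce, abs=1e-9)


def test_hybrid_loss_accepts_smoothed_targets():
    p = np.array([0.2, 0.2, 0.3, 0.3])
    ys = smooth_labels(np.array([0, 0, 1, 0.0]), 0.2)
    manual = 0.7 * -(
        (ys[2] + ys[3]) * np.log(0.6) + (ys[0] + ys[1]) * np.log(0.4)
    ) + 0.3 * -(ys * np.log(p)).sum()
    assert hybrid_loss(p, ys, 0.3) == pytest.approx(manual, abs=1e-9)


def test_hybrid_loss_grad_matches_finite_difference():
    z = np.array([0.3, -0.5, 0.8, 0.1])
    for alpha in (0.0, 0.3, 1.0):
        for y in (0, 2, smooth_labels(np.array([0, 1, 0, 0.0]), 0.2)):
            loss, dz = hybrid_loss_grad(z, y, alpha)
            eps = 1e-6
            for k in range(4):
                zp, zm = z.copy(), z.copy()
                zp[k] += eps
                zm[k] -= eps
                fd = (hybrid_loss_grad(zp, y, alpha)[0] - hybrid_loss_grad(zm, y, alpha)[0]) / (
                    2 * eps
                )
                assert dz[k] == pytest.approx(fd, abs=1e-6)


def test_loss_validates_inputs():
    with pytest.raises(ValueError):
        hybrid_loss(np.array([0.5, 0.5, 0.5, 0.5]), 0, 0.3)  # not a distribution
    with pytest.raises(ValueError):
        hybrid_loss(np.full(4, 0.25), 4, 0.3)  # label out of range
    with pytest.raises(ValueError):
        hybrid_loss(np.full(4, 0.25), 0, 1.5)  # alpha out of range


# ---------------------------------------------------------- label smoothing
def test_smooth_labels_values_and_sum():
    y = np.array([0, 0, 1, 0.0])
    np.testing.assert_allclose(smooth_labels(y, 0.2), [0.05, 0.05, 0.85, 0.05])
    np.testing.assert_allclose(smooth_labels(y, 0.0), y)
    assert smooth_labels(y, 0.37).sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        smooth_labels(y, 1.0)


# ---------------------------------------------------------------- schedule
def test_warmup_cosine_landmarks():
    cfg = TrainingConfig(epochs=100, max_lr=2e-4)
    assert lr_schedule(0, cfg) == 0.0
    assert lr_schedule(25, cfg) == pytest.approx(1e-4)  # linear ramp midpoint
    assert lr_schedule(50, cfg) == pytest.approx(2e-4)  # peak at T/2
    assert lr_schedule(75, cfg) == pytest.approx(1e-4)  # cosine midpoint
    assert lr_schedule(100, cfg) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        lr_schedule(101, cfg)


def test_cosine_decay_landmarks():
    cfg = TrainingConfig(scheduler="cosine_decay", cosine_lr0=5e-4, cosine_epochs=200)
    assert lr_schedule(0, cfg) == pytest.approx(5e-4)
    assert lr_schedule(100, cfg) == pytest.approx(2.5e-4)
    assert lr_schedule(200, cfg) == pytest.approx(0.0, abs=1e-12)


def test_schedule_continuous_at_peak():
    cfg = TrainingConfig(epochs=30)
    left = lr_schedule(15 - 1e-9, cfg)
    right = lr_schedule(15 + 1e-9, cfg)
    assert left == pytest.approx(right, abs=1e-9)


# --------------------------------------------------------- balanced epochs
def test_balanced_epoch_imbalanced_cohort():
    """Counts 12/82/123/61 (N=278): every class contributes m=round(N/4)=70."""
    labels = np.repeat([0, 1, 2, 3], [12, 82, 123, 61])
    seq = balanced_epoch(labels, seed=0)
    assert len(seq) == 280
    drawn = labels[seq]
    assert np.bincount(drawn, minlength=4).tolist() == [70, 70, 70, 70]
    # majority class sampled without replacement -> all indices distinct
    cls2 = seq[drawn == 2]
    assert len(np.unique(cls2)) == 70
    # minority class must repeat indices (12 originals for 70 slots)
    cls0 = seq[drawn == 0]
    assert len(np.unique(cls0)) <= 12


def test_balanced_epoch_deterministic_and_seed_sensitive():
    labels = np.repeat([0, 1, 2, 3], [3, 5, 4, 4])
    a = balanced_epoch(labels, seed=7)
    b = balanced_epoch(labels, seed=7)
    c = balanced_epoch(labels, seed=8)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)


def test_balanced_epoch_requires_all_classes():
    with pytest.raises(ValueError):
        balanced_epoch(np.array([0, 1, 1, 3]), seed=0)


# ------------------------------------------------------------ augmentation
def test_augment_zero_magnitude_is_identity():
    v = RNG.normal(size=(10, 12, 14)).astype(np.float32)
    p = AugmentationParams(
        translation_inplane=0, translation_slice=0, rotation_deg=0, scale_range=0, elastic=False
    )
    np.testing.assert_allclose(augment(v, p, seed=5), v, atol=1e-5)


def test_augment_deterministic_per_seed():
    v = RNG.normal(size=(10, 12, 14)).astype(np.float32)
    p = AugmentationParams()
    np.testing.assert_array_equal(augment(v, p, seed=3), augment(v, p, seed=3))
    assert not np.allclose(augment(v, p, seed=3), augment(v, p, seed=4))


def test_apply_transform_integer_shift_oracle():
    v = RNG.normal(size=(9, 11, 13)).astype(np.float32)
    out = apply_transform(v, translation=(2, 0, -1))
    # voxels inside the valid region are exact copies of the shifted source
    np.testing.assert_allclose(out[2:, :, :12], v[:7, :, 1:], atol=1e-5)
    # voxels shifted in from outside the volume are zero-filled
    assert np.abs(out[:2]).max() == 0.0


def test_augment_mask_stays_binary():
    v = RNG.normal(size=(12, 12, 12)).astype(np.float32)
    m = np.zeros_like(v, dtype=np.uint8)
    m[4:8, 4:8, 4:8] = 1
    out, mout = augment(v, AugmentationParams(), seed=1, mask=m)
    assert set(np.unique(mout)).issubset({0, 1})
    assert mout.sum() > 0


def test_scaled_for_width_shrinks_voxel_magnitudes():
    p = AugmentationParams().scaled_for_width(64)
    r = 64 / 180
    assert p.translation_inplane == pytest.approx(10 * r)
    assert p.translation_slice == pytest.approx(3 * r)
    assert p.bspline_perturb == pytest.approx(10 * r)
    assert p.rotation_deg == 20.0  # angles are grid-independent
    assert p.scale_range == 0.10


# ------------------------------------------------------------ training loop
def _tiny_dataset(n_per_class=2, seed=1):
    spec = PhantomSpec(shape=(12, 16, 16))
    return generate_dataset(n_per_class, seed=seed, spec=spec)[0]


def _tiny_config(**kw):
    base = dict(
        epochs=2,
        overlap=2,
        eval_every=1,
        aug=AugmentationParams(enabled=False),
    )
    base.update(kw)
    return TrainingConfig(**base)


TINY_BACKBONE = reduced_backbone(2)


def test_train_model_runs_and_logs():
    samples = _tiny_dataset()
    model, log = train_model(samples, _tiny_config(), seed=0, backbone=TINY_BACKBONE)
    assert list(log.columns) == ["epoch", "lr", "train_loss", "val_accuracy"]
    assert len(log) == 2
    assert np.isfinite(log["train_loss"]).all()
    assert model.train_metadata["seed"] == 0


def test_train_model_deterministic():
    samples = _tiny_dataset()
    m1, l1 = train_model(samples, _tiny_config(), seed=5, backbone=TINY_BACKBONE)
    m2, l2 = train_model(samples, _tiny_config(), seed=5, backbone=TINY_BACKBONE)
    for p, q in zip(m1.params(), m2.params()):
        np.testing.assert_array_equal(p.value, q.value)
    assert l1.equals(l2)


def test_train_model_seed_changes_weights():
    samples = _tiny_dataset()
    m1, _ = train_model(samples, _tiny_config(), seed=1, backbone=TINY_BACKBONE)
    m2, _ = train_model(samples, _tiny_config(), seed=2, backbone=TINY_BACKBONE)
    diff = any(not np.array_equal(p.value, q.value) for p, q in zip(m1.params(), m2.params()))
    assert diff


def test_cross_validate_table_and_best_epoch():
    samples = _tiny_dataset(n_per_class=2)
    cfg = _tiny_config(folds=2)
    table, best = cross_validate(samples, cfg, seed=0, backbone=TINY_BACKBONE)
    assert table.shape == (2, 2)
    assert list(table.columns) == ["fold_0", "fold_1"]
    # oracle: best epoch is the argmax of the mean accuracy across folds
    means = table.mean(axis=1)
    assert best == int(means.idxmax())
    assert 1 <= best <= cfg.epochs


def test_cross_validate_rejects_underfilled_classes():
    samples = _tiny_dataset(n_per_class=1)
    with pytest.raises(ValueError):
        cross_validate(samples, _tiny_config(folds=2), backbone=TINY_BACKBONE)


def test_train_ensemble_one_model_per_seed():
    samples = _tiny_dataset()
    cfg = _tiny_config(seeds=(0, 1), epochs=1)
    models = train_ensemble(samples, cfg, backbone=TINY_BACKBONE)
    assert len(models) == 2
    diff = any(
        not np.array_equal(p.value, q.value)
        for p, q in zip(models[0].params(), models[1].params())
    )
    assert diff
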