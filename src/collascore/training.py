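"""Training procedure: hybrid ordinal-aware loss, label smoothing, balanced
epochs, augmentation, one-cycle warm-up scheduling, Adam, cross-validation
and seed-varied ensembling.

The loss is a weighted combination of the binary cross-entropy on the
dichotomized prediction ``p23 = p2 + p3`` and the categorical cross-entropy
on the four-class prediction::

    L = (1 - alpha) * BCE(p23, y23) + alpha * CCE(p, y)

The binary term penalizes confusions that cross the clinically relevant
{0,1} vs {2,3} boundary more than neighbouring-class confusions, which makes
the four-level classification ordinal-aware.  Targets are label-smoothed,
``ys = (1 - s) * y + s / K`` with K the number of classes, and the
dichotomized target is derived from the smoothed vector (y23 = ys2 + ys3) so
both terms share one target.

The learning rate follows a single warm-up cycle: linear ramp to ``max_lr``
over the first half of training, then cosine decay to zero.  A plain cosine
decay is available as the ablation arm.  Each epoch draws the same number of
samples from every class (minority classes with replacement, majority
without), and every drawn sample is augmented with a random rigid + scaling
+ elastic (B-spline) transform applied to the full aligned volume before
hemisphere splitting, so the two hemispheres stay in voxelwise
correspondence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.model_selection import StratifiedKFold

from .network import BackboneConfig, ScoreDistribution, SiameseCollateralNet
from .nn import Adam, softmax
from .phantom import PhantomSample
from .preprocess import AlignedVolume, normalize_intensity, orient_affected_right, split_and_mirror

__all__ = [
    "AugmentationParams",
    "TrainingConfig",
    "hybrid_loss",
    "hybrid_loss_grad",
    "smooth_labels",
    "lr_schedule",
    "balanced_epoch",
    "augment",
    "apply_transform",
    "train_model",
    "cross_validate",
    "train_ensemble",
]

_CLIP = 1e-7


@dataclass(frozen=True)
class AugmentationParams:
    """Random-transform bounds, in voxels/degrees at the stated grid.

    Defaults are the clinical-grid values (~180 voxel wide 1 mm volumes):
    translation up to 10 voxels in-plane and 3 in the slice direction,
    rotation within +/-20 degrees in all planes, scaling within +/-10%, and
    an elastic B-spline deformation with a 20-voxel control-point spacing
    and per-point perturbations up to 10 voxels.  ``scaled_for_width``
    shrinks the voxel-valued magnitudes proportionally for smaller grids.
    """

    translation_inplane: float = 10.0
    translation_slice: float = 3.0
    rotation_deg: float = 20.0
    scale_range: float = 0.10
    bspline_spacing: float = 20.0
    bspline_perturb: float = 10.0
    bspline_degree: int = 1
    elastic: bool = True
    enabled: bool = True

    def scaled_for_width(self, width: int, reference_width: int = 180) -> "AugmentationParams":
        r = width / reference_width
        return dataclasses.replace(
            self,
            translation_inplane=self.translation_inplane * r,
            translation_slice=self.translation_slice * r,
            bspline_spacing=max(4.0, self.bspline_spacing * r),
            bspline_perturb=self.bspline_perturb * r,
        )


@dataclass(frozen=True)
class TrainingConfig:
    """Hyperparameters of one training run (defaults = full-model settings)."""

    alpha: float = 0.3
    smoothing: float = 0.2
    epochs: int = 100
    max_lr: float = 0.0002
    scheduler: str = "warmup_cosine"
    batch_size: int = 1
    aug: AugmentationParams = field(default_factory=AugmentationParams)
    seeds: tuple[int, ...] = (0, 1, 2)
    folds: int = 5
    n_classes: int = 4
    # cosine-decay ablation arm parameters
    cosine_lr0: float = 0.0005
    cosine_epochs: int = 200
    overlap: int = 10
    eval_every: int = 1
    whole_brain: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must be in [0, 1]")
        if not (0.0 <= self.smoothing < 1.0):
            raise ValueError("smoothing must be in [0, 1)")
        if self.scheduler not in ("warmup_cosine", "cosine_decay"):
            raise ValueError("scheduler must be 'warmup_cosine' or 'cosine_decay'")
        if self.epochs < 1 or self.folds < 2 or self.batch_size < 1:
            raise ValueError("epochs >= 1, folds >= 2, batch_size >= 1 required")


# --------------------------------------------------------------------- losses
def smooth_labels(y: np.ndarray, s: float) -> np.ndarray:
    """Label smoothing ``ys = (1 - s) * y + s / K`` for a one-hot vector."""
    y = np.asarray(y, dtype=np.float64)
    if not (0.0 <= s < 1.0):
        raise ValueError("smoothing must be in [0, 1)")
    k = y.shape[-1]
    return (1.0 - s) * y + s / k


def _as_probs(p) -> np.ndarray:
    if isinstance(p, ScoreDistribution):
        return p.probs
    arr = np.asarray(p, dtype=np.float64).reshape(-1)
    if arr.shape[0] != 4 or (arr < -1e-9).any() or abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError("invalid score distribution")
    return arr


def _as_target(y, n_classes: int = 4) -> np.ndarray:
    if np.ndim(y) == 0:
        c = int(y)
        if not 0 <= c < n_classes:
            raise ValueError(f"class label out of range: {c}")
        vec = np.zeros(n_classes)
        vec[c] = 1.0
        return vec
    return np.asarray(y, dtype=np.float64).reshape(n_classes)


def hybrid_loss(p, y, alpha: float) -> float:
    """Weighted binary + categorical cross-entropy (see module docstring).

    ``p`` is a 4-class distribution; ``y`` is a hard class label 0-3 or a
    (possibly smoothed) target vector.  Probabilities are clamped to
    ``[1e-7, 1 - 1e-7]`` before the logarithms.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must be in [0, 1]")
    probs = np.clip(_as_probs(p), _CLIP, 1.0 - _CLIP)
    target = _as_target(y)
    p23 = np.clip(probs[2] + probs[3], _CLIP, 1.0 - _CLIP)
    y23 = target[2] + target[3]
    bce = -(y23 * np.log(p23) + (1.0 - y23) * np.log(1.0 - p23))
    cce = -float(np.sum(target * np.log(probs)))
    return float((1.0 - alpha) * bce + alpha * cce)


def hybrid_loss_grad(logits: np.ndarray, y, alpha: float) -> tuple[float, np.ndarray]:
    """Loss value and its gradient w.r.t. the logits (p = softmax(logits))."""
    z = np.asarray(logits, dtype=np.float64).reshape(4)
    p = softmax(z)
    target = _as_target(y)
    loss = hybrid_loss(p, target, alpha)
    # categorical term: sum(target) = 1 for hard or smoothed targets
    dz = alpha * (p * target.sum() - target)
    p23 = np.clip(p[2] + p[3], _CLIP, 1.0 - _CLIP)
    y23 = target[2] + target[3]
    dldp23 = -(y23 / p23 - (1.0 - y23) / (1.0 - p23))
    ind = np.array([0.0, 0.0, 1.0, 1.0])
    dz += (1.0 - alpha) * dldp23 * p * (ind - (p[2] + p[3]))
    return loss, dz


# ------------------------------------------------------------------ schedule
def lr_schedule(t: float, config: TrainingConfig) -> float:
    """Learning rate at (possibly fractional) epoch ``t``.

    warmup_cosine: linear ramp to ``max_lr`` at T/2, then cosine decay to 0
    at T.  cosine_decay (ablation): ``lr0 * 0.5 * (1 + cos(pi * t / T))``.
    """
    if config.scheduler == "warmup_cosine":
        T = config.epochs
        if t < 0 or t > T:
            raise ValueError(f"epoch {t} outside [0, {T}]")
        half = T / 2.0
        if t <= half:
            return config.max_lr * t / half
        return config.max_lr * 0.5 * (1.0 + np.cos(np.pi * (t - half) / half))
    T = config.cosine_epochs
    if t < 0 or t > T:
        raise ValueError(f"epoch {t} outside [0, {T}]")
    return config.cosine_lr0 * 0.5 * (1.0 + np.cos(np.pi * t / T))


# ------------------------------------------------------------------ sampling
def balanced_epoch(labels, seed: int, n_classes: int = 4) -> np.ndarray:
    """Index sequence for one class-balanced epoch.

    Every class contributes exactly ``m = round(N / n_classes)`` indices:
    minority classes are up-sampled with replacement, majority classes
    down-sampled without.  The concatenated sequence is shuffled
    deterministically by ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    m = int(round(n / n_classes))
    rng = np.random.default_rng(seed)
    chunks = []
    for c in range(n_classes):
        idx = np.flatnonzero(labels == c)
        if len(idx) == 0:
            raise ValueError(f"class {c} has no samples; balanced epochs are impossible")
        if len(idx) >= m:
            chunks.append(rng.choice(idx, size=m, replace=False))
        else:
            chunks.append(rng.choice(idx, size=m, replace=True))
    seq = np.concatenate(chunks)
    rng.shuffle(seq)
    return seq


# -------------------------------------------------------------- augmentation
_COORD_CACHE: dict[tuple[int, int, int], np.ndarray] = {}


def _coords(shape: tuple[int, int, int]) -> np.ndarray:
    if shape not in _COORD_CACHE:
        _COORD_CACHE[shape] = np.indices(shape, dtype=np.float32).reshape(3, -1)
    return _COORD_CACHE[shape]


def _rotation_matrix(angles_deg) -> np.ndarray:
    ang = np.deg2rad(np.asarray(angles_deg, dtype=np.float64))

    def rot(a: float, i: int, j: int) -> np.ndarray:
        r = np.eye(3)
        r[i, i] = np.cos(a)
        r[i, j] = -np.sin(a)
        r[j, i] = np.sin(a)
        r[j, j] = np.cos(a)
        return r

    return rot(ang[0], 0, 1) @ rot(ang[1], 0, 2) @ rot(ang[2], 1, 2)


def _affine_src(shape, A: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Source coordinates of the center-anchored affine x -> A(x-c)+c+t."""
    shape_arr = np.array(shape, dtype=np.float64)
    c = (shape_arr - 1.0) / 2.0
    coords = _coords(shape)
    src = np.linalg.inv(A).astype(np.float32) @ (coords - (c + t)[:, None].astype(np.float32))
    src += c[:, None].astype(np.float32)
    return src


def apply_transform(
    volume: np.ndarray,
    translation=(0.0, 0.0, 0.0),
    rotation_deg=(0.0, 0.0, 0.0),
    scale=(1.0, 1.0, 1.0),
    mask: np.ndarray | None = None,
    cval: float = 0.0,
):
    """Deterministic center-anchored rigid+scale transform of a volume.

    Linear interpolation for intensities, nearest for the optional mask; an
    integer translation with no rotation/scale is an exact index shift
    inside the valid region.
    """
    A = _rotation_matrix(rotation_deg) @ np.diag(np.asarray(scale, dtype=np.float64))
    src = _affine_src(volume.shape, A, np.asarray(translation, dtype=np.float64))
    field_ = src.reshape(3, *volume.shape)
    out = ndimage.map_coordinates(np.asarray(volume, np.float32), field_, order=1, cval=cval)
    if mask is None:
        return out
    mout = ndimage.map_coordinates(np.asarray(mask, np.uint8), field_, order=0, cval=0)
    return out, mout


def _sample_displacement(
    shape: tuple[int, int, int], params: AugmentationParams, rng: np.random.Generator
) -> np.ndarray:
    """Source-coordinate field of a random rigid+scale+elastic transform.

    The affine part maps target voxel x to source A^{-1}(x - c - t) + c with
    rotations in all three planes, per-axis scaling and the translation
    bounds of ``params``; the elastic part adds a smooth displacement
    interpolated from a coarse control grid (a B-spline free-form
    deformation of degree ``params.bspline_degree``).
    """
    shape_arr = np.array(shape, dtype=np.float64)
    A = _rotation_matrix(rng.uniform(-params.rotation_deg, params.rotation_deg, size=3))
    A = A @ np.diag(rng.uniform(1.0 - params.scale_range, 1.0 + params.scale_range, size=3))
    t = np.array(
        [
            rng.uniform(-params.translation_inplane, params.translation_inplane),
            rng.uniform(-params.translation_inplane, params.translation_inplane),
            rng.uniform(-params.translation_slice, params.translation_slice),
        ]
    )
    src = _affine_src(shape, A, t)
    coords = _coords(shape)
    if params.elastic and params.bspline_perturb > 0:
        cg = np.maximum(2, np.ceil(shape_arr / params.bspline_spacing).astype(int) + 1)
        disp = rng.uniform(-params.bspline_perturb, params.bspline_perturb, size=(3, *cg))
        sc = ((cg - 1) / np.maximum(shape_arr - 1, 1)).astype(np.float32)
        cpts = (coords * sc[:, None]).reshape(3, *shape)
        for k in range(3):
            src[k] += ndimage.map_coordinates(
                disp[k].astype(np.float32), cpts, order=params.bspline_degree, mode="nearest"
            ).reshape(-1)
    return src.reshape(3, *shape)


def augment(
    volume: np.ndarray,
    params: AugmentationParams,
    seed: int,
    mask: np.ndarray | None = None,
    cval: float = 0.0,
) -> np.ndarray | tuple[np.ndarray, np.ndarray]:
    """Apply one random transform (deterministic per seed) to a full volume.

    Intensities are interpolated linearly, the mask (same field) with nearest
    neighbour.  Meant to run on the aligned volume *before* hemisphere
    splitting so the two halves stay in correspondence.
    """
    rng = np.random.default_rng(seed)
    field_ = _sample_displacement(volume.shape, params, rng)
    out = ndimage.map_coordinates(
        np.asarray(volume, dtype=np.float32), field_, order=1, cval=cval
    )
    if mask is None:
        return out
    mout = ndimage.map_coordinates(
        np.asarray(mask, dtype=np.uint8), field_, order=0, cval=0
    )
    return out, mout


# ------------------------------------------------------------- training loop
def _prepare_input(sample: PhantomSample | dict, config: TrainingConfig):
    """Aligned volume -> network input (pair or whole-brain volume+mask)."""
    if isinstance(sample, PhantomSample):
        vol, mask, side = sample.full_volume, sample.mca_mask, sample.affected_side
        spacing = sample.spacing
    else:
        vol, mask, side = sample["volume"], sample["mask"], sample["affected_side"]
        spacing = sample.get("spacing", (1.0, 1.0, 1.0))
    av = orient_affected_right(AlignedVolume(vol, spacing, side, mask))
    if config.whole_brain:
        return (normalize_intensity(av.voxels), av.mca_mask)
    return split_and_mirror(av, overlap=config.overlap)


def _augmented(sample, config: TrainingConfig, seed: int):
    if isinstance(sample, PhantomSample):
        vol, mask, side = sample.full_volume, sample.mca_mask, sample.affected_side
    else:
        vol, mask, side = sample["volume"], sample["mask"], sample["affected_side"]
    params = config.aug.scaled_for_width(vol.shape[0] // 2)
    avol, amask = augment(vol, params, seed, mask=mask)
    return {"volume": avol, "mask": amask, "affected_side": side}


def _labels_of(samples) -> np.ndarray:
    return np.array(
        [s.score if isinstance(s, PhantomSample) else s["score"] for s in samples]
    )


def evaluate_accuracy(model: SiameseCollateralNet, samples, config: TrainingConfig) -> float:
    """Multiclass accuracy by plain argmax over the predicted distribution."""
    labels = _labels_of(samples)
    preds = []
    for s in samples:
        dist = model.predict(_prepare_input(s, config))
        preds.append(int(np.argmax(dist.probs)))
    return float(np.mean(np.array(preds) == labels))


def train_model(
    samples,
    config: TrainingConfig,
    seed: int = 0,
    val_samples=None,
    backbone: BackboneConfig | None = None,
) -> tuple[SiameseCollateralNet, pd.DataFrame]:
    """Train one model; deterministic per seed.

    ``samples`` is a sequence of :class:`~collascore.phantom.PhantomSample`
    or dicts with keys volume/mask/affected_side/score.  Returns the trained
    model and a per-epoch log (epoch, lr, mean train loss, val accuracy).
    """
    if len(samples) == 0:
        raise ValueError("empty training set")
    labels = _labels_of(samples)
    ss = np.random.SeedSequence([seed, 0x5C0])
    init_seed, epoch_seed0 = [int(s) for s in ss.generate_state(2) % (2**31 - 1)]
    model = SiameseCollateralNet(backbone, whole_brain=config.whole_brain, seed=init_seed)
    opt = Adam(model.params(), lr=0.0)
    rows = []
    for epoch in range(config.epochs):
        order = balanced_epoch(labels, seed=epoch_seed0 + epoch, n_classes=config.n_classes)
        losses = []
        aug_rng = np.random.default_rng(epoch_seed0 + 7919 * (epoch + 1))
        for step, idx in enumerate(order):
            t = epoch + step / max(len(order), 1)
            opt.lr = lr_schedule(min(t, config.epochs), config)
            s = samples[idx]
            if config.aug.enabled:
                s = _augmented(s, config, seed=int(aug_rng.integers(2**31 - 1)))
            x = _prepare_input(s, config)
            z = model.forward_logits(x, keep_cache=True)
            y = smooth_labels(_as_target(labels[idx]), config.smoothing)
            loss, dz = hybrid_loss_grad(z, y, config.alpha)
            opt.zero_grad()
            model.backward_from_logits(dz)
            opt.step()
            losses.append(loss)
        val_acc = np.nan
        if val_samples is not None and (
            (epoch + 1) % config.eval_every == 0 or epoch == config.epochs - 1
        ):
            val_acc = evaluate_accuracy(model, val_samples, config)
        rows.append(
            {
                "epoch": epoch + 1,
                "lr": lr_schedule(epoch + 1, config),
                "train_loss": float(np.mean(losses)),
                "val_accuracy": val_acc,
            }
        )
    log = pd.DataFrame(rows)
    model.train_metadata = {  # type: ignore[attr-defined]
        "alpha": config.alpha,
        "smoothing": config.smoothing,
        "seed": seed,
        "epochs": config.epochs,
        "scheduler": config.scheduler,
    }
    return model, log


def cross_validate(
    samples,
    config: TrainingConfig,
    seed: int = 0,
    backbone: BackboneConfig | None = None,
) -> tuple[pd.DataFrame, int]:
    """Stratified k-fold cross-validation.

    Returns the epoch-by-fold validation-accuracy table and the epoch
    (1-based) maximizing the mean validation multiclass accuracy across
    folds — the epoch count used for final training.
    """
    labels = _labels_of(samples)
    counts = np.bincount(labels, minlength=config.n_classes)
    if (counts < config.folds).any():
        missing = np.flatnonzero(counts < config.folds)
        raise ValueError(
            f"classes {missing.tolist()} have fewer samples than folds={config.folds}; "
            "stratification would leave a fold without them"
        )
    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=seed)
    cols = {}
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        _, log = train_model(
            [samples[i] for i in tr],
            config,
            seed=seed + fold,
            val_samples=[samples[i] for i in va],
            backbone=backbone,
        )
        cols[f"fold_{fold}"] = log["val_accuracy"].to_numpy()
    table = pd.DataFrame(cols, index=pd.RangeIndex(1, config.epochs + 1, name="epoch"))
    best_epoch = int(table.mean(axis=1).idxmax())
    return table, best_epoch


def train_ensemble(
    samples,
    config: TrainingConfig,
    val_samples=None,
    backbone: BackboneConfig | None = None,
) -> list[SiameseCollateralNet]:
    """One model per seed in ``config.seeds``, differing only in the random
    processes (initialization, balancing, augmentation)."""
    if len(config.seeds) < 1:
        raise ValueError("need at least one seed")
    return [
        train_model(samples, config, seed=s, val_samples=val_samples, backbone=backbone)[0]
        for s in config.seeds
    ]
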