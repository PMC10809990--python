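"""Siamese 3D residual network for collateral scoring.

Two weight-sharing branches of a VoxResNet-style volumetric residual backbone
extract one feature map per hemisphere at half the input resolution.  Each
feature map is masked with the (downsampled) MCA-territory mask and reduced
to a feature vector by global average pooling; the two vectors are
concatenated (affected first, healthy second) and a single fully connected
layer with softmax produces the four class probabilities.

Because the final layer is linear and pooling is a masked average, applying
the layer per voxel instead of to the pooled vectors yields a class
activation map (CAM) whose masked spatial mean reproduces each class logit
exactly; this is how :func:`compute_cam` provides voxel-wise class evidence.

Instance normalization is used throughout (the model trains with unit-sized
mini-batches), and the backbone's deeper stage runs at quarter resolution and
is fused back into the half-resolution stream by nearest-neighbour
upsampling, so the exported features always live on the half-resolution grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .nn import Conv3d, InstanceNorm3d, Layer, Linear, Param, ReLU, UpsampleNearest, softmax
from .preprocess import HemispherePair

__all__ = [
    "BackboneConfig",
    "ScoreDistribution",
    "CAMStack",
    "SiameseCollateralNet",
    "masked_gap",
    "downsample_mask",
    "classify",
    "classify_whole_brain",
    "compute_cam",
    "average_cams",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Backbone layout.

    ``n_features`` is the number of Siamese features representing each
    hemisphere (28 in the full model).  ``blocks`` gives the number of
    residual blocks at each resolution level below full resolution: the first
    entry at 1/2 resolution, the (optional) second at 1/4 resolution whose
    output is upsampled and added back to the 1/2-resolution stream.
    ``full_res_stem`` selects the two full-resolution stem convolutions of
    the reference layout; switching it off moves the stem's stride-2
    downsampling into the first convolution, which is much cheaper on CPU and
    is the default for the reduced phantom-scale model.
    """

    n_features: int = 28
    blocks: tuple[int, ...] = (2, 2)
    full_res_stem: bool = True
    instance_norm_eps: float = 1e-5

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        if len(self.blocks) not in (1, 2):
            raise ValueError("blocks must have one or two resolution levels")

    @property
    def n_levels(self) -> int:
        return len(self.blocks)

    @property
    def min_input_size(self) -> int:
        return 2 ** self.n_levels


@dataclass
class ScoreDistribution:
    """Four collateral-class probabilities and the derived dichotomized one."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64).reshape(4)
        if (self.probs < -1e-9).any() or (self.probs > 1 + 1e-9).any():
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {self.probs.sum()}")

    @property
    def p23(self) -> float:
        """Probability of good collaterals (dichotomized classes 2+3)."""
        return float(self.probs[2] + self.probs[3])

    def __getitem__(self, c: int) -> float:
        return float(self.probs[c])


@dataclass
class CAMStack:
    """Per-class activation volumes at feature-map (half) resolution.

    ``class_maps`` includes the classifier bias as a constant offset so that
    the masked spatial mean of map ``c`` equals logit ``c``.  For the Siamese
    model the per-hemisphere contributions are kept separately (without
    bias).
    """

    class_maps: np.ndarray  # (4, d, h, w)
    mask: np.ndarray  # (d, h, w) bool, feature resolution
    logits: np.ndarray  # (4,)
    affected_contrib: np.ndarray | None = None
    healthy_contrib: np.ndarray | None = None

    def masked_mean(self, c: int) -> float:
        return float(self.class_maps[c][self.mask].mean())


class _VoxResBlock(Layer):
    """Pre-activation residual block: x + conv(relu(IN(conv(relu(IN(x))))))."""

    def __init__(self, channels: int, eps: float, rng: np.random.Generator, name: str) -> None:
        self.in_a = InstanceNorm3d(channels, eps, name=f"{name}.in_a")
        self.relu_a = ReLU()
        self.conv_a = Conv3d(channels, channels, 3, rng=rng, name=f"{name}.conv_a")
        self.in_b = InstanceNorm3d(channels, eps, name=f"{name}.in_b")
        self.relu_b = ReLU()
        self.conv_b = Conv3d(channels, channels, 3, rng=rng, name=f"{name}.conv_b")

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in (self.in_a, self.conv_a, self.in_b, self.conv_b):
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv_a.forward(self.relu_a.forward(self.in_a.forward(x)))
        h = self.conv_b.forward(self.relu_b.forward(self.in_b.forward(h)))
        return x + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.in_b.backward(self.relu_b.backward(self.conv_b.backward(dy)))
        dh = self.in_a.backward(self.relu_a.backward(self.conv_a.backward(dh)))
        return dy + dh


class _Sequential(Layer):
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class _VoxResBackbone(Layer):
    """Volumetric residual feature extractor; output at 1/2 resolution."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        f, eps = cfg.n_features, cfg.instance_norm_eps
        if cfg.full_res_stem:
            self.stem = _Sequential(
                [
                    Conv3d(1, f, 3, rng=rng, name="conv1a", input_grad=False),
                    InstanceNorm3d(f, eps, name="in1"),
                    ReLU(),
                    Conv3d(f, f, 3, rng=rng, name="conv1b"),
                    InstanceNorm3d(f, eps, name="in2"),
                    ReLU(),
                    Conv3d(f, f, 3, stride=2, rng=rng, name="down1"),
                ]
            )
        else:
            self.stem = _Sequential(
                [Conv3d(1, f, 3, stride=2, rng=rng, name="down1", input_grad=False)]
            )
        self.blocks0 = _Sequential(
            [_VoxResBlock(f, eps, rng, name=f"res0_{i}") for i in range(cfg.blocks[0])]
        )
        self.deep: _Sequential | None = None
        self.up: UpsampleNearest | None = None
        if cfg.n_levels > 1:
            self.deep = _Sequential(
                [
                    InstanceNorm3d(f, eps, name="in_d2"),
                    ReLU(),
                    Conv3d(f, f, 3, stride=2, rng=rng, name="down2"),
                ]
                + [_VoxResBlock(f, eps, rng, name=f"res1_{i}") for i in range(cfg.blocks[1])]
            )
            self.up = UpsampleNearest(2)
        self.head = _Sequential([InstanceNorm3d(f, eps, name="in_head"), ReLU()])

    def params(self) -> list[Param]:
        out = self.stem.params() + self.blocks0.params()
        if self.deep is not None:
            out += self.deep.params()
        return out + self.head.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.blocks0.forward(self.stem.forward(x))
        if self.deep is not None:
            assert self.up is not None
            h = h + self.up.forward(self.deep.forward(h))
        return self.head.forward(h)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.head.backward(dy)
        if self.deep is not None:
            assert self.up is not None
            dh = dh + self.deep.backward(self.up.backward(dh))
        return self.stem.backward(self.blocks0.backward(dh))


def pad_to_multiple(vol: np.ndarray, multiple: int, fill: float = -1.0) -> np.ndarray:
    """Pad spatial dims at the high end so each is a multiple of ``multiple``."""
    pads = [(0, (-s) % multiple) for s in vol.shape]
    if not any(p[1] for p in pads):
        return vol
    return np.pad(vol, pads, constant_values=fill)


def downsample_mask(mask: np.ndarray, factor: int = 2) -> np.ndarray:
    """Resample a binary mask to feature resolution by block max-pooling:
    any covered voxel marks the downsampled voxel (preserves thin coverage)."""
    m = pad_to_multiple(np.asarray(mask) > 0, factor, fill=0)
    d, h, w = m.shape
    f = factor
    return m.reshape(d // f, f, h // f, f, w // f, f).any(axis=(1, 3, 5))


def masked_gap(fmap: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Per-feature mean over mask voxels.

    ``fmap`` is ``(C, d, h, w)`` or ``(N, C, d, h, w)``; ``mask`` is a binary
    ``(d, h, w)`` array at the same (feature) resolution.  Voxels outside the
    mask contribute to neither numerator nor denominator.
    """
    m = np.asarray(mask) > 0
    if int(m.sum()) == 0:
        raise ValueError("empty mask: masked pooling is undefined")
    if fmap.ndim == 4:
        return fmap[:, m].mean(axis=1)
    if fmap.ndim == 5:
        return fmap[:, :, m].mean(axis=2)
    raise ValueError("feature map must be 4D (C,d,h,w) or 5D (N,C,d,h,w)")


class SiameseCollateralNet:
    """The full classifier: shared backbone, masked GAP, linear head, softmax.

    With ``whole_brain=True`` the same backbone is applied once to the entire
    (unsplit) preprocessed volume and pooled over the both-hemisphere mask —
    the non-Siamese ablation arm.  The backbone parameter count is identical
    in both arms; only the head width differs (2F vs F inputs).
    """

    N_CLASSES = 4

    def __init__(
        self,
        cfg: BackboneConfig | None = None,
        *,
        whole_brain: bool = False,
        seed: int = 0,
    ) -> None:
        self.cfg = cfg or BackboneConfig()
        self.whole_brain = whole_brain
        rng = np.random.default_rng(seed)
        self.backbone = _VoxResBackbone(self.cfg, rng)
        head_in = self.cfg.n_features * (1 if whole_brain else 2)
        self.head = Linear(head_in, self.N_CLASSES, rng=rng, name="fc")
        self._cache: dict | None = None

    # ------------------------------------------------------------------ params
    def params(self) -> list[Param]:
        return self.backbone.params() + self.head.params()

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # ----------------------------------------------------------------- forward
    def _check_size(self, shape: tuple[int, ...]) -> None:
        mn = self.cfg.min_input_size
        if any(s < mn for s in shape):
            raise ValueError(
                f"input spatial dims {shape} too small for {self.cfg.n_levels} "
                f"down-sampling stage(s); every dim must be >= {mn}"
            )

    def _prepare(self, pair_or_vol) -> tuple[np.ndarray, np.ndarray]:
        """Stack branch inputs (N,1,D,H,W) and the feature-resolution mask."""
        mult = self.cfg.min_input_size
        if self.whole_brain:
            vol, mask = pair_or_vol
            self._check_size(vol.shape)
            x = pad_to_multiple(np.asarray(vol, dtype=np.float32), mult)[None, None]
            m = pad_to_multiple(np.asarray(mask) > 0, mult, fill=0)
        else:
            pair: HemispherePair = pair_or_vol
            self._check_size(pair.affected.shape)
            aff = pad_to_multiple(pair.affected.astype(np.float32), mult)
            heal = pad_to_multiple(pair.healthy_mirrored.astype(np.float32), mult)
            x = np.stack([aff, heal])[:, None]
            m = pad_to_multiple(pair.mca_mask_half > 0, mult, fill=0)
        return x, downsample_mask(m, 2)

    def extract_features(self, half: np.ndarray) -> np.ndarray:
        """Backbone feature map of a single normalized hemisphere volume,
        ``(n_features, D/2, H/2, W/2)`` after padding to even dims."""
        self._check_size(half.shape)
        x = pad_to_multiple(np.asarray(half, dtype=np.float32), self.cfg.min_input_size)
        return self.backbone.forward(x[None, None])[0]

    def forward_logits(self, pair_or_vol, *, keep_cache: bool = False) -> np.ndarray:
        x, mask_ds = self._prepare(pair_or_vol)
        fmap = self.backbone.forward(x)
        v = masked_gap(fmap, mask_ds)  # (N, F)
        feat = v.reshape(1, -1)
        z = self.head.forward(feat)[0]
        if keep_cache:
            self._cache = {"fmap_shape": fmap.shape, "mask_ds": mask_ds}
        return z

    def backward_from_logits(self, dz: np.ndarray) -> None:
        """Backpropagate a gradient w.r.t. the logits through head + backbone."""
        assert self._cache is not None, "call forward_logits(keep_cache=True) first"
        dfeat = self.head.backward(np.asarray(dz, dtype=np.float32).reshape(1, -1))
        n, c = self._cache["fmap_shape"][:2]
        dv = dfeat.reshape(n, c)
        mask_ds = self._cache["mask_ds"]
        n_vox = int(mask_ds.sum())
        dfmap = np.zeros(self._cache["fmap_shape"], dtype=np.float32)
        dfmap[:, :, mask_ds] = dv[:, :, None] / n_vox
        self.backbone.backward(dfmap)
        self._cache = None

    def predict(self, pair_or_vol) -> ScoreDistribution:
        z = self.forward_logits(pair_or_vol)
        return ScoreDistribution(softmax(z.astype(np.float64)))

    # --------------------------------------------------------------------- CAM
    def compute_cam(self, pair_or_vol) -> CAMStack:
        """Class activation maps: the final layer applied per voxel to the
        feature maps instead of to the pooled vectors."""
        x, mask_ds = self._prepare(pair_or_vol)
        fmap = self.backbone.forward(x).astype(np.float64)
        w = self.head.weight.value.astype(np.float64)  # (4, F or 2F)
        b = self.head.bias.value.astype(np.float64)
        f = self.cfg.n_features
        if self.whole_brain:
            aff = heal = None
            cams = np.einsum("cf,fdhw->cdhw", w, fmap[0]) + b[:, None, None, None]
        else:
            aff = np.einsum("cf,fdhw->cdhw", w[:, :f], fmap[0])
            heal = np.einsum("cf,fdhw->cdhw", w[:, f:], fmap[1])
            cams = aff + heal + b[:, None, None, None]
        logits = np.array([cams[c][mask_ds].mean() for c in range(self.N_CLASSES)])
        return CAMStack(
            class_maps=cams,
            mask=mask_ds,
            logits=logits,
            affected_contrib=aff,
            healthy_contrib=heal,
        )


# ------------------------------------------------------------- functional API
def classify(pair: HemispherePair, model: SiameseCollateralNet) -> ScoreDistribution:
    """Score distribution for a preprocessed hemisphere pair."""
    if model.whole_brain:
        raise ValueError("model is the whole-brain arm; use classify_whole_brain")
    return model.predict(pair)


def classify_whole_brain(
    vol: np.ndarray, mask: np.ndarray, model: SiameseCollateralNet
) -> ScoreDistribution:
    """Score distribution for a full preprocessed (unsplit) volume."""
    if not model.whole_brain:
        raise ValueError("model is Siamese; use classify")
    return model.predict((vol, mask))


def compute_cam(pair_or_vol, model: SiameseCollateralNet) -> CAMStack:
    return model.compute_cam(pair_or_vol)


def average_cams(cams: list[CAMStack]) -> CAMStack:
    """Ensemble CAM: arithmetic mean of the member activation maps."""
    if not cams:
        raise ValueError("need at least one CAM")

    def _mean(arrs):
        return None if arrs[0] is None else np.mean(arrs, axis=0)

    return CAMStack(
        class_maps=np.mean([c.class_maps for c in cams], axis=0),
        mask=cams[0].mask,
        logits=np.mean([c.logits for c in cams], axis=0),
        affected_contrib=_mean([c.affected_contrib for c in cams]),
        healthy_contrib=_mean([c.healthy_contrib for c in cams]),
    )


# ----------------------------------------------------------------- checkpoints
def save_checkpoint(model: SiameseCollateralNet, path, metadata: dict | None = None) -> None:
    """Serialize weights + config (+ arbitrary JSON metadata) to one file."""
    arrays = {f"param_{i:03d}": p.value for i, p in enumerate(model.params())}
    meta = {
        "config": asdict(model.cfg),
        "whole_brain": model.whole_brain,
        "metadata": metadata or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[SiameseCollateralNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        cfg_dict = dict(meta["config"])
        cfg_dict["blocks"] = tuple(cfg_dict["blocks"])
        model = SiameseCollateralNet(
            BackboneConfig(**cfg_dict), whole_brain=meta["whole_brain"]
        )
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i:03d}"]
    return model, meta["metadata"]
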