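"""Synthetic paired-hemisphere CTA phantoms with known collateral scores.

The generator emulates the geometry the collateral score is defined on: two
hemispheres with soft-tissue background, an ellipsoidal vascular territory
placed symmetrically and laterally in each hemisphere (a crude analogue of the
atlas MCA territory), and bright tubular vessel structures.  The healthy
hemisphere's territory is fully vascularized; the affected hemisphere contains
a controllable fraction ``f`` of the healthy side's vascularized volume, which
maps to the 4-level collateral score:

* ``f = 0``            -> score 0 (no collateral filling)
* ``0 < f < 0.5``      -> score 1 (less than half the territory filled)
* ``0.5 <= f < 1``     -> score 2 (more than half filled)
* ``f = 1``            -> score 3 (completely vascularized)

Vessels are straight tubes of 1-2 voxel radius with random orientation —
enough to create the hemispheric vessel-signal asymmetry the classifier and
its class-activation maps respond to, without attempting vascular-tree
realism.  Intensities default to ~40 HU tissue and ~300 HU vessel so they
straddle the [35, 165] HU normalization window used downstream (vessels
saturate to +1).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PhantomSpec",
    "PhantomSample",
    "score_from_fraction",
    "generate_phantom",
    "generate_dataset",
    "measured_filling_ratio",
]

_ENDPOINT_EPS = 1e-6


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a single phantom.

    ``shape`` is the per-hemisphere voxel grid ``(nx, ny, nz)`` with the first
    axis left-right; the full volume is two hemispheres concatenated along
    that axis.  The grid is 1 mm isotropic by convention.
    """

    shape: tuple[int, int, int] = (32, 48, 48)
    territory_fraction: float = 0.30
    filling_fraction: float = 1.0
    vessel_intensity: float = 300.0
    tissue_intensity: float = 40.0
    noise_sd: float = 5.0
    vessel_volume_fraction: float = 0.25
    affected_side: str = "right"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.filling_fraction <= 1.0):
            raise ValueError(f"filling_fraction must be in [0, 1], got {self.filling_fraction}")
        if not (0.0 < self.territory_fraction < 1.0):
            raise ValueError("territory_fraction must be in (0, 1)")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ValueError("hemisphere shape must be 3D with all dims >= 8")


@dataclass
class PhantomSample:
    """A generated phantom: full volume, symmetric territory mask, labels."""

    full_volume: np.ndarray
    mca_mask: np.ndarray
    affected_side: str
    score: int
    filling_fraction: float
    spec: PhantomSpec

    @property
    def spacing(self) -> tuple[float, float, float]:
        return (1.0, 1.0, 1.0)


def score_from_fraction(f: float) -> int:
    """Map a territory filling fraction onto the 4-level collateral score."""
    if not np.isfinite(f) or f < -_ENDPOINT_EPS or f > 1.0 + _ENDPOINT_EPS:
        raise ValueError(f"filling fraction must be in [0, 1], got {f}")
    if f <= _ENDPOINT_EPS:
        return 0
    if f >= 1.0 - _ENDPOINT_EPS:
        return 3
    return 1 if f < 0.5 else 2


def _territory_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal territory in the LEFT hemisphere grid, shifted laterally.

    Semi-axes are proportional to the hemisphere dims, scaled so the ellipsoid
    volume approximates ``territory_fraction`` of the hemisphere (the caller
    fixes the fraction through the proportionality constant).
    """
    nx, ny, nz = shape
    # proportionality constant for a 0.30 volume fraction: (6*frac/pi)^(1/3)
    k = (6.0 * 0.30 / np.pi) ** (1.0 / 3.0)
    a, b, c = k * nx / 2.0, k * ny / 2.0, k * nz / 2.0
    # lateral shift: move center toward the outer (low-x) side of the left
    # hemisphere while keeping the ellipsoid inside the grid
    shift = max(0.0, (nx / 2.0 - a) / 2.0)
    cx, cy, cz = (nx - 1) / 2.0 - shift, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.indices(shape, dtype=np.float32)
    e = ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2
    return e <= 1.0


def _ball_offsets(radius: int) -> np.ndarray:
    r = int(radius)
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[keep], dy[keep], dz[keep]], axis=1)


def _draw_tube(rng: np.random.Generator, territory_idx: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    """One straight tube inside the territory; ordered array of voxel coords."""
    center = territory_idx[rng.integers(len(territory_idx))]
    direction = rng.standard_normal(3)
    direction /= np.linalg.norm(direction) + 1e-12
    length = rng.uniform(0.4, 1.0) * min(shape)
    radius = int(rng.integers(1, 3))  # 1 or 2 voxels
    ts = np.arange(-length / 2.0, length / 2.0, 0.5)
    centers = np.round(center[None, :] + ts[:, None] * direction[None, :]).astype(np.int64)
    offs = _ball_offsets(radius)
    vox = (centers[:, None, :] + offs[None, :, :]).reshape(-1, 3)
    # keep order along the tube, drop duplicates and out-of-territory voxels
    inb = np.all((vox >= 0) & (vox < np.array(shape)), axis=1)
    vox = vox[inb]
    _, first = np.unique(vox, axis=0, return_index=True)
    vox = vox[np.sort(first)]
    return vox


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom; fully determined by ``spec`` (including seed)."""
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    terr = _territory_mask(spec.shape)
    terr_idx = np.argwhere(terr)
    if len(terr_idx) < 30:
        raise ValueError("territory too small to place a vessel; enlarge the hemisphere shape")

    # --- healthy-side vessels: tubes until the territory is 'fully' vascularized
    target_healthy = max(1, int(round(spec.vessel_volume_fraction * len(terr_idx))))
    healthy = np.zeros(spec.shape, dtype=bool)
    tubes: list[np.ndarray] = []
    guard = 0
    while healthy.sum() < target_healthy and guard < 10_000:
        guard += 1
        vox = _draw_tube(rng, terr_idx, spec.shape)
        if len(vox) == 0:
            continue
        intr = terr[vox[:, 0], vox[:, 1], vox[:, 2]]
        vox = vox[intr]
        if len(vox) == 0:
            continue
        new = ~healthy[vox[:, 0], vox[:, 1], vox[:, 2]]
        if not new.any():
            continue
        tubes.append(vox[new])
        healthy[vox[new, 0], vox[new, 1], vox[new, 2]] = True
    n_healthy = int(healthy.sum())
    if n_healthy == 0:
        raise ValueError("failed to place any vessel inside the territory")

    # --- affected-side vessels: mirrored tube subset trimmed to exactly
    # round(f * n_healthy) voxels, preserving tube structure
    f = spec.filling_fraction
    target_affected = int(round(f * n_healthy))
    affected = np.zeros(spec.shape, dtype=bool)
    placed = 0
    for vox in tubes:
        if placed >= target_affected:
            break
        take = min(len(vox), target_affected - placed)
        v = vox[:take]
        affected[v[:, 0], v[:, 1], v[:, 2]] = True
        placed += take

    # --- assemble full volume: healthy = left hemisphere, affected = right
    full_shape = (2 * nx, ny, nz)
    vol = np.full(full_shape, spec.tissue_intensity, dtype=np.float32)
    mask = np.zeros(full_shape, dtype=np.uint8)
    mask[:nx][terr] = 1
    mask[nx:][terr[::-1]] = 1  # mirror about the mid-sagittal plane
    vol[:nx][healthy] = spec.vessel_intensity
    vol[nx:][affected[::-1]] = spec.vessel_intensity
    if spec.noise_sd > 0:
        vol += rng.normal(0.0, spec.noise_sd, size=full_shape).astype(np.float32)

    side = "right"
    if spec.affected_side == "left":
        vol = vol[::-1].copy()
        mask = mask[::-1].copy()
        side = "left"

    return PhantomSample(
        full_volume=vol,
        mca_mask=mask,
        affected_side=side,
        score=score_from_fraction(f),
        filling_fraction=f,
        spec=spec,
    )


def measured_filling_ratio(sample: PhantomSample) -> float:
    """Vascularized-volume ratio affected/healthy measured from the voxels.

    Vessel voxels are those above the tissue/vessel midpoint intensity inside
    the territory mask.  Used to verify the generator against its own ``f``.
    """
    thr = 0.5 * (sample.spec.tissue_intensity + sample.spec.vessel_intensity)
    nx = sample.full_volume.shape[0] // 2
    left = (sample.full_volume[:nx] > thr) & (sample.mca_mask[:nx] > 0)
    right = (sample.full_volume[nx:] > thr) & (sample.mca_mask[nx:] > 0)
    if sample.affected_side == "right":
        healthy_n, affected_n = left.sum(), right.sum()
    else:
        healthy_n, affected_n = right.sum(), left.sum()
    if healthy_n == 0:
        raise ValueError("no vascularized voxels on the healthy side")
    return float(affected_n) / float(healthy_n)


# class bands for sampling f; small margins keep realized fractions strictly
# inside each band under voxel quantization
_CLASS_BANDS = {0: (0.0, 0.0), 1: (0.02, 0.48), 2: (0.52, 0.98), 3: (1.0, 1.0)}


def generate_dataset(
    n_per_class: int,
    seed: int = 0,
    spec: PhantomSpec | None = None,
) -> tuple[list[PhantomSample], pd.DataFrame]:
    """Generate a class-balanced phantom dataset plus its manifest table.

    Each score class contributes exactly ``n_per_class`` samples; ``f`` is
    sampled uniformly inside the class band, and the affected side is
    randomized left/right.  The manifest records id, affected side, f, score
    and the per-sample seed, so every sample is reproducible in isolation.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    template = spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    samples: list[PhantomSample] = []
    rows = []
    i = 0
    for cls in range(4):
        lo, hi = _CLASS_BANDS[cls]
        for _ in range(n_per_class):
            f = float(lo if lo == hi else rng.uniform(lo, hi))
            side = "left" if rng.random() < 0.5 else "right"
            sseed = int(rng.integers(0, 2**31 - 1))
            s = dataclasses.replace(
                template, filling_fraction=f, affected_side=side, seed=sseed
            )
            sample = generate_phantom(s)
            samples.append(sample)
            rows.append(
                {
                    "id": f"phantom_{i:04d}",
                    "affected_side": side,
                    "f": f,
                    "score": sample.score,
                    "seed": sseed,
                }
            )
            i += 1
    manifest = pd.DataFrame(rows)
    return samples, manifest


def save_dataset(samples: list[PhantomSample], manifest: pd.DataFrame, outdir) -> pd.DataFrame:
    """Write volumes/masks as NIfTI (1 mm isotropic) and the manifest as CSV."""
    import os

    import nibabel as nib

    os.makedirs(outdir, exist_ok=True)
    affine = np.eye(4)
    manifest = manifest.copy()
    paths, mask_paths = [], []
    for i, s in enumerate(samples):
        pid = manifest.iloc[i]["id"]
        p = os.path.join(outdir, f"{pid}.nii.gz")
        mp = os.path.join(outdir, f"{pid}_mask.nii.gz")
        nib.save(nib.Nifti1Image(s.full_volume.astype(np.float32), affine), p)
        nib.save(nib.Nifti1Image(s.mca_mask.astype(np.uint8), affine), mp)
        paths.append(p)
        mask_paths.append(mp)
    manifest["path"] = paths
    manifest["mask_path"] = mask_paths
    cols = ["id", "path", "mask_path", "affected_side", "f", "score", "seed"]
    manifest = manifest[cols]
    manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    return manifest
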