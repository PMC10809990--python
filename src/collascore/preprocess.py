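"""Hemisphere preprocessing for CTA collateral scoring.

Operates on volumes already aligned to a 1 mm isotropic atlas space (the
diffeomorphic registration producing that alignment is an external step; see
:func:`registration_hook`).  The steps implemented here are:

1. flip the volume so the affected hemisphere is always on the image-right
   side (high index along the left-right axis),
2. split the volume into two hemisphere sub-images with a small overlap so
   each branch of the Siamese network has mid-line context,
3. mirror the healthy hemisphere to obtain voxel-wise correspondence with the
   affected one,
4. window the intensities to [35, 165] HU and map them linearly onto [-1, 1],
   clipping values outside the window.

All arrays are indexed ``(x, y, z)`` with ``x`` the left-right axis under the
RAS convention (low x = left).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "AlignedVolume",
    "HemispherePair",
    "normalize_intensity",
    "orient_affected_right",
    "split_and_mirror",
    "scale_overlap",
    "registration_hook",
    "HU_WINDOW",
]

#: intensity window mapped onto [-1, 1]; chosen to give good contrast between
#: brain tissue and contrast-enhanced vessels (vessels saturate to +1)
HU_WINDOW = (35.0, 165.0)

#: overlap between the two hemisphere sub-images at the reference 1 mm
#: clinical grid (~180 voxels wide); scaled for smaller grids
REFERENCE_OVERLAP = 10
REFERENCE_WIDTH = 180


@dataclass
class AlignedVolume:
    """Atlas-aligned HU volume with its territory mask and affected side."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affected_side: str
    mca_mask: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        self.mca_mask = np.asarray(self.mca_mask)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.voxels.ndim}")
        if self.mca_mask.shape != self.voxels.shape:
            raise ValueError("mask grid must equal image grid")
        if self.affected_side not in ("left", "right"):
            raise ValueError("affected_side must be 'left' or 'right'")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")


@dataclass
class HemispherePair:
    """Affected half and mirrored healthy half in voxelwise correspondence.

    Both members are normalized to [-1, 1]; ``mca_mask_half`` lives on the
    affected half's grid (which, after mirroring, is also the healthy one's).
    """

    affected: np.ndarray
    healthy_mirrored: np.ndarray
    mca_mask_half: np.ndarray
    overlap_voxels: int

    def __post_init__(self) -> None:
        if self.affected.shape != self.healthy_mirrored.shape:
            raise ValueError("pair members must have identical shape")
        if self.mca_mask_half.shape != self.affected.shape:
            raise ValueError("half mask must live on the affected half's grid")
        for name, arr in (("affected", self.affected), ("healthy_mirrored", self.healthy_mirrored)):
            if arr.min() < -1.0 - 1e-6 or arr.max() > 1.0 + 1e-6:
                raise ValueError(f"{name} intensities outside [-1, 1]; normalize first")


def normalize_intensity(values: np.ndarray | float) -> np.ndarray | float:
    """Map HU values linearly from [35, 165] onto [-1, 1], clipping outside.

    35 HU -> -1, 165 HU -> +1, 100 HU -> 0.
    """
    arr = np.asarray(values, dtype=np.float32)
    if np.isnan(arr).any():
        raise ValueError("NaN intensities cannot be normalized")
    lo, hi = HU_WINDOW
    out = np.clip(2.0 * (arr - lo) / (hi - lo) - 1.0, -1.0, 1.0).astype(np.float32)
    if np.isscalar(values) or np.ndim(values) == 0:
        return float(out)
    return out


def orient_affected_right(vol: AlignedVolume) -> AlignedVolume:
    """Flip about the mid-sagittal plane so the affected hemisphere is on the
    image-right side; right-affected input is returned unchanged."""
    if vol.affected_side == "right":
        return vol
    return AlignedVolume(
        voxels=vol.voxels[::-1].copy(),
        spacing=vol.spacing,
        affected_side="right",
        mca_mask=vol.mca_mask[::-1].copy(),
    )


def scale_overlap(width: int) -> int:
    """Overlap scaled proportionally from the 10-voxel reference at the
    ~180-voxel clinical grid, at least 1 voxel."""
    return max(1, int(round(REFERENCE_OVERLAP * width / REFERENCE_WIDTH)))


def split_and_mirror(vol: AlignedVolume, overlap: int = REFERENCE_OVERLAP) -> HemispherePair:
    """Split an affected-right volume into hemisphere halves, mirror the
    healthy one, and normalize intensities.

    Each half is ``ceil(W/2) + overlap`` voxels wide.  The mirrored healthy
    half is in voxelwise correspondence with the affected half: index ``i``
    of both halves refers to mirror-symmetric positions about the volume's
    mid-sagittal plane.
    """
    if vol.affected_side != "right":
        raise ValueError("apply orient_affected_right before splitting")
    w = vol.voxels.shape[0]
    if overlap < 0:
        raise ValueError("overlap must be nonnegative")
    if w < 2 * overlap or (w + 1) // 2 + overlap > w:
        raise ValueError(f"volume of width {w} is too narrow for an overlap of {overlap}")
    half_w = (w + 1) // 2 + overlap  # ceil(W/2) + overlap
    affected = vol.voxels[w - half_w :]
    healthy = vol.voxels[:half_w][::-1]
    mask_half = vol.mca_mask[w - half_w :]
    return HemispherePair(
        affected=normalize_intensity(affected),
        healthy_mirrored=normalize_intensity(healthy),
        mca_mask_half=(mask_half > 0).astype(np.uint8),
        overlap_voxels=overlap,
    )


def registration_hook(image_path: str, atlas_path: str) -> None:
    """Placeholder for the external atlas-alignment step.

    Alignment of raw CTA to the atlas (multi-step affine plus diffeomorphic
    registration, with resampling to 1 mm isotropic) is performed outside
    this package, e.g. with the ANTs toolkit::

        antsRegistrationSyN.sh -d 3 -f <atlas> -m <cta> -o <prefix>

    This package consumes the pre-aligned output.
    """
    raise NotImplementedError(
        "atlas registration is delegated to an external tool (e.g. ANTs); "
        "provide pre-aligned volumes"
    )
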