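"""NIfTI and manifest I/O.

Volumes are canonicalized to RAS orientation on load, so the first array
axis is always left-right (low index = left) and flips about the
mid-sagittal plane are well defined.  Manifests are plain CSV tables with
columns id, path, mask_path, affected_side and optionally score and fold.
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import AlignedVolume

__all__ = ["load_volume", "save_volume", "load_manifest", "load_manifest_samples"]

_ANISOTROPY_TOL = 0.05


def load_volume(path, mask_path=None, affected_side: str = "right") -> AlignedVolume:
    """Load a NIfTI volume (and optional mask) as an RAS-oriented volume.

    Rejects non-3D images; warns (via ValueError-free check) when the voxel
    spacing deviates from isotropic by more than 5%.
    """
    img = nib.load(os.fspath(path))
    if img.ndim != 3:
        raise ValueError(f"expected a 3D image, got {img.ndim}D: {path}")
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj).astype(np.float32)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if max(spacing) / min(spacing) > 1.0 + _ANISOTROPY_TOL:
        import warnings

        warnings.warn(
            f"anisotropic voxels {spacing}; the model assumes ~1 mm isotropic input",
            stacklevel=2,
        )
    if mask_path is not None:
        mimg = nib.load(os.fspath(mask_path))
        if mimg.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {mimg.ndim}D: {mask_path}")
        mimg = nib.as_closest_canonical(mimg)
        mask = (np.asanyarray(mimg.dataobj) > 0).astype(np.uint8)
        if mask.shape != data.shape:
            raise ValueError("mask grid does not match image grid")
    else:
        mask = np.ones_like(data, dtype=np.uint8)
    return AlignedVolume(voxels=data, spacing=spacing, affected_side=affected_side, mca_mask=mask)


def save_volume(array: np.ndarray, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write an array as NIfTI with a diagonal RAS affine."""
    affine = np.diag([*spacing, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array), affine), os.fspath(path))


def load_manifest(path, check_files: bool = True) -> pd.DataFrame:
    """Load and validate a manifest CSV."""
    df = pd.read_csv(path)
    required = {"id", "path", "mask_path", "affected_side"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        raise ValueError("manifest ids must be unique")
    if not df["affected_side"].isin(["left", "right"]).all():
        raise ValueError("affected_side must be 'left' or 'right'")
    if "score" in df.columns and df["score"].notna().any():
        sc = df["score"].dropna()
        if not sc.isin([0, 1, 2, 3]).all():
            raise ValueError("scores must be in 0-3")
    if check_files:
        base = os.path.dirname(os.fspath(path))
        for col in ("path", "mask_path"):
            for p in df[col]:
                full = p if os.path.isabs(p) else os.path.join(base, p)
                if not os.path.exists(full):
                    raise FileNotFoundError(f"manifest references missing file: {p}")
    return df


def load_manifest_samples(path) -> list[dict]:
    """Materialize manifest rows as in-memory training samples."""
    df = load_manifest(path)
    base = os.path.dirname(os.fspath(path))

    def _full(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    out = []
    for _, row in df.iterrows():
        av = load_volume(_full(row["path"]), _full(row["mask_path"]), row["affected_side"])
        out.append(
            {
                "id": row["id"],
                "volume": av.voxels,
                "mask": av.mca_mask,
                "affected_side": row["affected_side"],
                "score": int(row["score"]) if "score" in row and pd.notna(row["score"]) else None,
                "spacing": av.spacing,
            }
        )
    return out
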