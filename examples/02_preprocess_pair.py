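"""From an aligned volume to the Siamese network's hemisphere pair.

Preprocessing mirrors the clinical pipeline once registration to a 1 mm
atlas has been done elsewhere: flip so the affected hemisphere is on the
image-right side, split into two overlapping halves, mirror the healthy
half into voxelwise correspondence with the affected one, and window
intensities from [35, 165] HU onto [-1, 1].

Run:  python examples/02_preprocess_pair.py
"""

import numpy as np

from collascore import PhantomSpec, generate_phantom
from collascore.preprocess import (
    AlignedVolume,
    orient_affected_right,
    scale_overlap,
    split_and_mirror,
)

sample = generate_phantom(
    PhantomSpec(shape=(32, 48, 48), filling_fraction=0.3, affected_side="left", seed=5)
)

vol = AlignedVolume(
    voxels=sample.full_volume,
    spacing=sample.spacing,
    affected_side=sample.affected_side,
    mca_mask=sample.mca_mask,
)

# 1. affected hemisphere to the image-right side
vol = orient_affected_right(vol)
print(f"affected side after orientation : {vol.affected_side}")

# 2./3./4. split + mirror + normalize; overlap scaled from the clinical grid
overlap = scale_overlap(vol.voxels.shape[0])
pair = split_and_mirror(vol, overlap=overlap)
print(f"full width                      : {vol.voxels.shape[0]} voxels")
print(f"overlap                         : {pair.overlap_voxels} voxels")
print(f"half shape                      : {pair.affected.shape}  (= ceil(W/2) + overlap)")
print(f"affected intensity range        : {pair.affected.min():.2f} .. {pair.affected.max():.2f}")

# voxelwise correspondence: index i in both halves refers to mirror-symmetric
# positions, so a difference map highlights the missing collateral filling
diff = pair.healthy_mirrored - pair.affected
inside = pair.mca_mask_half > 0
print(f"mean healthy-minus-affected in territory : {diff[inside].mean():.3f} (positive = deficit)")
print(f"mean outside territory                   : {diff[~inside].mean():.3f}")
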