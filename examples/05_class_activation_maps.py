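"""Class activation maps: where the model finds its evidence.

Because the classifier head is a single linear layer on a masked spatial
average, applying that layer per voxel instead of after pooling yields one
evidence map per class whose masked spatial mean exactly reproduces the
corresponding logit.  For the Siamese model the map decomposes into an
affected-hemisphere and a healthy-hemisphere contribution.

Run:  python examples/05_class_activation_maps.py
"""

import numpy as np

from collascore import PhantomSpec, generate_phantom
from collascore.network import SiameseCollateralNet, average_cams
from collascore.pipeline import reduced_backbone
from collascore.preprocess import AlignedVolume, orient_affected_right, split_and_mirror

sample = generate_phantom(PhantomSpec(shape=(16, 24, 24), filling_fraction=0.2, seed=9))
vol = AlignedVolume(sample.full_volume, sample.spacing, sample.affected_side, sample.mca_mask)
pair = split_and_mirror(orient_affected_right(vol), overlap=2)

# an untrained model already demonstrates the exact CAM identity ------------
model = SiameseCollateralNet(reduced_backbone(4), seed=1)
logits = model.forward_logits(pair)
cam = model.compute_cam(pair)

print("CAM identity: masked mean of each class map == logit")
for c in range(4):
    print(f"  class {c}: logit {logits[c]:+.6f}   masked CAM mean {cam.masked_mean(c):+.6f}")

print(f"\nCAM stack shape        : {cam.class_maps.shape} (class, half-resolution grid)")
print(f"mask voxels at feature resolution: {int(cam.mask.sum())}")

# per-hemisphere decomposition ----------------------------------------------
assert cam.affected_contrib is not None and cam.healthy_contrib is not None
recon = cam.affected_contrib + cam.healthy_contrib + model.head.bias.value[:, None, None, None]
print(f"affected + healthy + bias == class map: max |error| = "
      f"{np.abs(recon - cam.class_maps).max():.2e}")

# ensembles average their CAMs voxelwise -------------------------------------
other = SiameseCollateralNet(reduced_backbone(4), seed=2)
avg = average_cams([cam, other.compute_cam(pair)])
print(f"ensemble CAM logits    : {np.round(avg.logits, 4)}")
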