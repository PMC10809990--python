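"""Generate a small collateral-phantom dataset and inspect it.

The phantom generator builds paired-hemisphere CTA-like volumes: an
ellipsoidal vascular territory placed symmetrically in both hemispheres, a
healthy hemisphere filled with bright tubular "vessels", and an affected
hemisphere whose vessel tree is a mirrored subset trimmed so the
vascularized-volume ratio equals a requested filling fraction f.  The
4-level collateral score follows from f alone:

    f = 0        -> 0 (no filling)
    0 < f < 0.5  -> 1 (less than half)
    0.5 <= f < 1 -> 2 (more than half)
    f = 1        -> 3 (complete)

Run:  python examples/01_generate_phantoms.py
"""

import numpy as np

from collascore import PhantomSpec, generate_dataset, generate_phantom
from collascore.phantom import measured_filling_ratio, save_dataset

# one phantom, fully specified -----------------------------------------------
spec = PhantomSpec(shape=(32, 48, 48), filling_fraction=0.6, affected_side="right", seed=42)
sample = generate_phantom(spec)
print(f"volume shape          : {sample.full_volume.shape}  (two hemispheres, x first)")
print(f"requested f           : {spec.filling_fraction}")
print(f"measured ratio        : {measured_filling_ratio(sample):.4f}")
print(f"collateral score      : {sample.score}")
print(f"territory voxels/hemi : {int(sample.mca_mask.sum()) // 2}")
print(f"intensity range (HU)  : {sample.full_volume.min():.0f} .. {sample.full_volume.max():.0f}")

# a balanced dataset with manifest --------------------------------------------
samples, manifest = generate_dataset(n_per_class=3, seed=7, spec=PhantomSpec(shape=(16, 24, 24)))
print("\nbalanced dataset (3 per class):")
print(manifest[["id", "affected_side", "f", "score"]].to_string(index=False))
print("\nclass counts:", np.bincount(manifest["score"], minlength=4).tolist())

# write to disk as NIfTI + CSV (uncomment to persist)
# save_dataset(samples, manifest, "phantoms_out")
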