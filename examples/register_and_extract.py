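"""Register one subject onto the target mask and extract its 1998 features.

Shows the two-stage registration (affine, then demons refinement) and the
layered-histogram feature vector computed in target space.
"""

import numpy as np

from renaltlco import PhantomSpec, generate_phantom, make_target_mask
from renaltlco.features import extract_features, feature_names
from renaltlco.registration import register_subject

target = make_target_mask(image_size=(96, 96), kidney_axes=(34.0, 20.0), bend=0.3)
subject = generate_phantom(
    PhantomSpec(
        subject_id="demo", true_egfr=45.0, image_size=(96, 96),
        kidney_axes=(30.0, 19.0), bend=0.42, noise_sigma=10.0, cyst_count=1,
        rng_seed=7,
    )
)
s = subject.analysis_slice
mask = subject.mask.labels[s] > 0

registered = register_subject(subject.volume.slices[s], mask, target)
print(f"mask overlap (Dice) after affine: {registered.dice_affine:.4f}")
print(f"mask overlap (Dice) after demons: {registered.dice_final:.4f}")

image = np.where(registered.mask, registered.image, 0.0)
vec = extract_features(image, registered.mask, target.layers)
names = feature_names()
print(f"\nfeature vector length: {len(vec)}")
for k in (1, 6, 12):
    v = vec[names.index(f"orig/layer_median/{k}")]
    print(f"  median intensity, layer {k:2d}: {v:8.2f}")
print(
    "\nLayer medians rise from cortex to medulla because the phantom's\n"
    "intensity ramp (steepness ~ eGFR) is sampled through the target's\n"
    "precomputed 12-layer map."
)
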