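"""Twelve-layer concentric parcellation of a kidney phantom.

Generates a noiseless bean-shaped phantom whose intensity ramps with
concentric depth, computes the geodesic 12-layer map, and prints the
corticomedullary layer statistics.
"""

import numpy as np

from renaltlco import PhantomSpec, compute_layer_map, generate_phantom, layer_statistics

spec = PhantomSpec(true_egfr=90.0, noise_sigma=0.0, cyst_count=0)
phantom = generate_phantom(spec)
s = phantom.analysis_slice
mask = phantom.mask.labels[s] > 0
layers = compute_layer_map(mask)

print(f"phantom kidney: {int(mask.sum())} pixels, planted eGFR {spec.true_egfr}")
counts = np.bincount(layers[mask], minlength=13)[1:]
print("pixels per layer (1 = outer cortex ... 12 = inner medulla):")
print(" ", counts.tolist())

stats = layer_statistics(phantom.volume.slices[s], layers)
print(f"\ncortical mean  (layers 1-3):  {stats.cortical_mean:8.2f}")
print(f"medullary mean (layers 8-10): {stats.medullary_mean:8.2f}")
print(f"gradient (layers 4-7):        {stats.gradient:8.4f} intensity per % depth")
print(
    "\nThe gradient quantifies cortex-medulla contrast; in this phantom it is\n"
    f"proportional to the planted eGFR (link: {spec.gradient_per_layer:.2f} per layer)."
)
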