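"""Simulate a PlanetScope-like scene and inspect its ground truth.

Generates one 4-band (NIR, red, green, blue) 3 m reflectance scene of a
fire-affected forest landscape with contiguous and fragmented burnt
patches, a water body, shadow regions and a blocky coarse-grid forest
mask, then prints the landscape composition.
"""

import numpy as np

from burntseg import SceneParams, generate_scene
from burntseg.synthetic import CLASS_NAMES

params = SceneParams(height=256, width=256, burnt_fraction_target=0.157, seed=7)
scene, truth = generate_scene(params)

print(f"scene: {scene.shape[0]} x {scene.shape[1]} px at {scene.pixel_size_m} m")
print(f"clipped reflectance fraction: {scene.meta['clip_fraction']:.4f}")
for code, name in CLASS_NAMES.items():
    share = float(np.mean(truth.class_map == code))
    print(f"  {name:<11} {share * 100:5.1f} % of pixels")

burnt_of_forest = truth.burnt.sum() / truth.forest_mask.sum()
print(f"burnt share of forest: {burnt_of_forest * 100:.1f} % "
      f"(target {params.burnt_fraction_target * 100:.1f} %)")
nir = scene.band("nir")
print(f"mean NIR reflectance, burnt {nir[truth.burnt == 1].mean():.3f} "
      f"vs vegetation {nir[truth.class_map == 1].mean():.3f} "
      "(burns depress NIR strongly)")
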