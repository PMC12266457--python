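"""Derive a threshold-based burnt-area reference mask.

Emulates the analyst workflow on a single post-fire image: sample band
values at labelled burnt/unburnt points, record each band's min/max over
the burnt samples, then mark every pixel whose four band values all fall
inside those ranges and that lies inside the forest mask.
"""

import numpy as np

from burntseg import (SceneParams, generate_scene, extract_band_ranges,
                      sample_raster_values, threshold_mask, confusion, metrics)
from burntseg.refmask import SampleSet

scene, truth = generate_scene(SceneParams(height=256, width=256, seed=3))

rng = np.random.default_rng(0)
burnt_px = np.argwhere(truth.burnt == 1)
unburnt_px = np.argwhere((truth.forest_mask == 1) & (truth.burnt == 0))
points = [(int(r), int(c), "burnt")
          for r, c in burnt_px[rng.choice(len(burnt_px), 200, replace=False)]]
points += [(int(r), int(c), "unburnt")
           for r, c in unburnt_px[rng.choice(len(unburnt_px), 200, replace=False)]]

table = sample_raster_values(scene, SampleSet(points=points))
ranges = extract_band_ranges(table, "burnt")
print("per-band burnt reflectance ranges (min, max):")
for band, (lo, hi) in ranges.ranges.items():
    print(f"  {band:<6} [{lo:.3f}, {hi:.3f}]")

mask = threshold_mask(scene, ranges, truth.forest_mask)
m = metrics(confusion(mask, truth.burnt))
print(f"reference mask vs simulated truth: IoU {m['iou_burnt']:.3f}, "
      f"dice {m['dice']:.3f} — the threshold mask recovers most burnt pixels; "
      "disagreements sit on spectral-range boundaries.")
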