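"""Generate one synthetic cotton-plot scene and inspect its ground truth.

The generator renders soil, green vegetation, light-brown woody segments and
white bolls with known per-pixel classes, so every later pipeline stage can
be scored against exact truth.
"""

import numpy as np

from bollcount.synthetic_fixtures import CLASS_NAMES, SceneConfig, generate_scene

scene = generate_scene(SceneConfig(height=256, width=256, n_bolls=60, seed=7))

print(f"scene {scene.image.plot_id}: "
      f"{scene.image.shape[0]}x{scene.image.shape[1]} px, "
      f"{scene.true_count} bolls placed")
for cid, name in CLASS_NAMES.items():
    frac = float(np.mean(scene.class_map == cid))
    print(f"  {name:<11s} {frac * 100:5.1f}% of pixels")
radii = [r for _, r in scene.boll_truth]
print(f"boll radii: {min(radii):.1f}-{max(radii):.1f} px")
# The class fractions show the scene composition; the boll list is the exact
# count the counting pipeline should recover.
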