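"""Color-index background removal on a synthetic plot.

Vegetation is removed where the modified excess-green index exceeds 0;
surviving soil is removed where the CIELAB soil index falls below 0.35.
Only a few percent of pixels — boll cores plus some woody confusers —
reach the classifier.
"""

import numpy as np

from bollcount import color_features as cf
from bollcount.synthetic_fixtures import CLASS_COTTON, SceneConfig, generate_scene
from bollcount.types import reduction_report

scene = generate_scene(SceneConfig(seed=7))
bg = cf.background_mask(scene.image, veg_threshold=0.0, soil_threshold=0.35)

print(reduction_report(bg.raw_pixels, bg.after_vegetation, bg.after_soil))

cotton = scene.class_map == CLASS_COTTON
kept = bg.retained.astype(bool)
print(f"cotton pixels kept:    {100 * (kept & cotton).sum() / cotton.sum():.1f}%")
print(f"non-cotton among kept: {100 * (kept & ~cotton).sum() / kept.sum():.1f}%")
# The first percentage shows boll cores survive the index thresholds; the
# second is the residual the SVM classifier has to reject.
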