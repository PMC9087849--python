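# Methods

## Pipeline model and assumptions

`bollcount` estimates plot-level cotton yield as the number of open bolls
visible in a nadir RGB image of the plot. The method assumes (i) bolls are
the brightest, least chromatic objects in the scene; (ii) vegetation is
distinguishable by green dominance; (iii) soil is distinguishable by a
reddish-brown cast in CIELAB; and (iv) one annotated plot is representative
enough to train a pixel classifier for the whole trial. Counting equates
bolls with 8-connected pixel clusters after morphological cleanup, so
touching bolls are counted once — an intrinsic under-count mode in dense
canopies, reported rather than corrected.

## Background removal

Two indices are computed per pixel:

* `ExGR_mod = 2.5 g − 3 r − b` on chromatic coordinates
  r = R/(R+G+B) etc. The chromatic form makes the index invariant to
  uniform intensity scaling; its range is [−3, 2.5]. Pixels with
  `ExGR_mod > veg_threshold` are removed as vegetation.
* `Soil_Idx = 0.5 L*/100 − 2 a*/127 + b*/127` from CIELAB (sRGB transfer,
  D65). The component maxima (100 for L*, 127 for a*/b*) put all three
  terms on comparable unitless scales; min–max scaling per image was the
  alternative and was rejected because it makes the index
  scene-dependent. Surviving pixels with `Soil_Idx < soil_threshold` are
  removed as soil.

Defaults: `veg_threshold = 0.0` (the classic sign convention of
excess-green-minus-excess-red segmentation) and `soil_threshold = 0.35`.
The soil threshold is a calibration constant fixed against the synthetic
palettes before any end-to-end run: the soil palette's maximum index is
0.341 and the boll-core minimum is ≈ 0.40, so 0.35 removes essentially all
soil while keeping boll cores. Both thresholds and both comparison
directions are exposed in `PipelineConfig` because real scenes (different
soils, illumination) will need recalibration. Pixels with R+G+B = 0 carry
index 0 and are always removed: they are the zero fill produced by polygon
clipping, and must never enter training.

Boll rims deliberately fall below the soil threshold (see the generator's
lightness falloff), so detection is partial at boll edges; this emulates
the reduced reflectance of lower-canopy bolls and is why counting relies
on cores rather than complete silhouettes.

## Pixel classifier

Retained pixels form a table of 9 color features (R, G, B, H, S, V, L*,
a*, b*) plus coordinates and, for the training plot, a binary label taken
from the annotation mask. Choices that matter:

* **Split.** 4:1 train:test with `train = floor(0.8 N)`, seeded
  unstratified shuffle. At N = 34,212 retained pixels this yields the
  27,369/6,843 partition.
* **Feature selection.** Recursive feature elimination, one feature per
  round, importance from a 100-tree random forest (impurity-based,
  seeded), down to k = 4 features. Only the 9 color channels are
  candidates; coordinates are bookkeeping, not features.
* **SVM.** RBF kernel, C = 1.0, γ = "scale" = 1/(k · Var(X)). No feature
  standardization: the "scale" bandwidth absorbs overall feature scale,
  and adding a scaler would silently change the model class. No class
  weighting; the resulting precision/recall trade-off is part of the
  method's reported behavior.
* **Metrics.** Accuracy, precision, recall, F1 and Type I/II error rates
  from the test-subset confusion matrix, as percentages. Type I = 100 −
  precision, Type II = 100 − recall, exactly. Zero-denominator cases
  return NaN rather than raising, so batch runs never crash on degenerate
  plots.

## Morphology and counting

Erosion with the 3×3 "elliptic" element — whose discrete form is the
5-pixel cross — then dilation with the 5×5 rectangle. Border convention:
outside-image pixels are background for erosion (border foreground
erodes) and contribute nothing to dilation. A single stray pixel dies
under erosion; two objects whose gap after erosion is ≤ 4 px merge under
the 5×5 dilation. Components are labeled with 8-connectivity and
renumbered by first raster-scan encounter so outputs are deterministic;
`min_area` (default 1, i.e. off) is an extensibility knob, not part of
the reference procedure.

## Evaluation statistics

* The OLS fit is predicted-on-truth; residuals are fit residuals, whose
  mean is 0 by construction. NRMSE and MAPE are computed from the raw
  prediction errors (truth vs pipeline count), not from the fit:
  NRMSE = RMSE/(y_max − y_min) of the ground truth, MAPE in percent,
  undefined (NaN) when the truth range is zero or any truth count is 0.
* Outliers: |residual − mean| > 3 SD, flagged but retained in the
  reported fit; `refit_without_outliers` recomputes the line without
  them.
* One-way ANOVA by the classical sum-of-squares decomposition; the
  all-identical degenerate case returns F = 0, p = 1.
* Fisher's LSD uses the pooled error mean square and its df:
  LSD(i,j) = t(1−α/2, df_w) · √(MSW (1/nᵢ + 1/nⱼ)). Letters are assigned
  by sorting means descending and marking maximal runs of mutually
  non-different groups — the conventional agronomic display. The
  guarantee is one-directional: groups sharing a letter are never
  significantly different; a non-significant pair may still fail to share
  a letter when non-significance is not interval-shaped along the sorted
  means. Genotypes with a single replicate get NaN SE and no letter.

## Synthetic scene generator

`synthetic_fixtures` renders the four scene elements with palettes chosen
in CIELAB so class separability lives in the space the classifier uses:

| element | palette | role |
| --- | --- | --- |
| soil | L* 45–62, a* 10–16, b* 12–24 | removed by Soil_Idx (max index 0.341 < 0.35) |
| vegetation | G 100–180 with R, B ≤ 0.55 G | removed by ExGR_mod (> 0 by construction) |
| wood | L* 62–75, a* 6–12, b* 18–28 | straddles the soil threshold: the Type-I confuser the SVM must reject |
| cotton | center L* 85–98, a* −3–1, b* −1–5, linear falloff of 25 L* to the rim | cores retained, rims lost: the Type-II mechanism |

Bolls are disks (radius default 2.5–4 px) placed by rejection sampling
with a per-boll retry cap of 10,000; `min_separation` is the gap between
disk boundaries, so any positive value makes the disks pairwise disjoint.
Soil texture and final RGB noise both scale with `noise_sd` (default 2
intensity units), so a zero-noise scene renders exact palette colors. An
optional multiplicative left-right lightness ramp (`illumination_gradient`)
emulates uneven illumination; default 0.

Scenes are desk scale by design — 256×256 for training fixtures, up to
448×448 for evaluation plots (the package's choice of problem size;
roughly 1/8 the linear extent of a field plot image). What the generator
does **not** emulate: shadows and specular highlights, mixed
boundary-pixel colors from optical blur, orthomosaic stitching seams,
radiometric drift across a flight, and partially occluded bolls. On these
clean scenes the pixel classes are nearly separable, so classifier metrics
sit near 100% and count recovery is near perfect (R² > 0.99, MAPE < 2% in
the shipped acceptance run); passing here validates the machinery and its
determinism, not field-condition accuracy, where the same pipeline is
expected to trade recall for precision under shading.

## Numerical conventions

* Hue of achromatic pixels is 0; HSV and CIELAB via scikit-image (sRGB,
  D65).
* Structuring elements must have odd sides; the discrete ellipse always
  includes its center.
* Probabilistic outputs (SVM class probabilities) use Platt scaling as
  fitted by the underlying SVC; all seeds flow from a single
  configuration seed, and derived seeds stay below 2³¹.
* Percentages in reduction reports are printed to two decimals;
  statistical p-values are reported to machine precision with no
  multiple-testing correction beyond the LSD's own design.
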