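"""Color spaces, background-removal indices, and per-pixel feature extraction.

Two scalar color indices drive background removal before any learning:

* ``exgr_mod`` — a modified excess-green-minus-excess-red index over the
  chromatic coordinates R/(R+G+B), G/(R+G+B), B/(R+G+B):
  ``2.5*G_norm - 3*R_norm - B_norm``.  Vegetation scores high (up to 2.5 for
  pure green); near-neutral pixels sit at -0.5; pure red at -3.
* ``soil_idx`` — a CIELAB-based index ``0.5*L_norm - 2*a_norm + b_norm`` with
  L* normalized by 100 and a*, b* by 127.  Reddish-brown soil scores low
  (the -2*a term dominates); bright low-chroma cotton scores high.

Pixels with R+G+B == 0 (the zero fill produced by polygon clipping) carry
index value 0 and are always removed.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from skimage.color import rgb2hsv, rgb2lab

from .types import AnnotationMask, BackgroundMask, PlotImage, ValidationError

#: column order of the feature table (11 columns with coordinates)
FEATURE_TABLE_COLUMNS = ["row", "col", "R", "G", "B", "H", "S", "V", "L", "a", "b"]

#: the 9 color-channel feature names eligible for selection
COLOR_FEATURES = ["R", "G", "B", "H", "S", "V", "L", "a", "b"]


def to_hsv(image: PlotImage) -> np.ndarray:
    """Hexcone HSV from unit-scaled RGB; all components in [0, 1].

    Hue of achromatic pixels is 0.
    """
    return rgb2hsv(image.pixels / 255.0)


def to_cielab(image: PlotImage) -> np.ndarray:
    """CIELAB (D65, sRGB transfer): L* in [0, 100], a*/b* opponent axes."""
    return rgb2lab(image.pixels / 255.0)


def exgr_mod(image: PlotImage) -> np.ndarray:
    """Modified ExG-ExR vegetation index per pixel; 0 where R+G+B == 0."""
    rgb = image.pixels.astype(np.float64)
    total = rgb.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = rgb / total[:, :, None]
    idx = 2.5 * norm[:, :, 1] - 3.0 * norm[:, :, 0] - norm[:, :, 2]
    idx[total == 0] = 0.0
    return idx


def soil_idx(image: PlotImage) -> np.ndarray:
    """CIELAB soil index per pixel; 0 where R+G+B == 0."""
    lab = to_cielab(image)
    idx = 0.5 * lab[:, :, 0] / 100.0 - 2.0 * lab[:, :, 1] / 127.0 + lab[:, :, 2] / 127.0
    idx[image.pixels.sum(axis=2) == 0] = 0.0
    return idx


def background_mask(
    image: PlotImage, veg_threshold: float = 0.0, soil_threshold: float = 0.35
) -> BackgroundMask:
    """Two-stage background removal.

    Stage 1 removes vegetation: pixels with ``exgr_mod > veg_threshold``.
    Stage 2 removes soil among the survivors: pixels with
    ``soil_idx < soil_threshold``.  Degenerate (0,0,0) pixels are always
    removed.  Per-stage pixel counts are recorded for reduction reporting.
    """
    if not (np.isfinite(veg_threshold) and np.isfinite(soil_threshold)):
        raise ValidationError("thresholds must be finite")
    nonzero = image.pixels.sum(axis=2) > 0
    raw = int(image.pixels.shape[0] * image.pixels.shape[1])
    veg_kept = nonzero & (exgr_mod(image) <= veg_threshold)
    soil_kept = veg_kept & (soil_idx(image) >= soil_threshold)
    return BackgroundMask(
        retained=soil_kept.astype(np.uint8),
        raw_pixels=raw,
        after_vegetation=int(veg_kept.sum()),
        after_soil=int(soil_kept.sum()),
    )


def extract_features(
    image: PlotImage,
    retained: BackgroundMask,
    annotation: Optional[AnnotationMask] = None,
) -> pd.DataFrame:
    """Build the per-retained-pixel feature table.

    One row per retained pixel with columns row, col, R, G, B, H, S, V, L, a,
    b; a ``label`` column (1 = cotton) is attached from the annotation mask
    when provided.
    """
    if retained.retained.shape != image.shape:
        raise ValidationError(
            f"background mask shape {retained.retained.shape} != image {image.shape}"
        )
    if annotation is not None and annotation.mask.shape != image.shape:
        raise ValidationError(
            f"annotation shape {annotation.mask.shape} != image {image.shape}"
        )
    rows, cols = np.nonzero(retained.retained)
    hsv = to_hsv(image)
    lab = to_cielab(image)
    data = {
        "row": rows,
        "col": cols,
        "R": image.pixels[rows, cols, 0].astype(np.float64),
        "G": image.pixels[rows, cols, 1].astype(np.float64),
        "B": image.pixels[rows, cols, 2].astype(np.float64),
        "H": hsv[rows, cols, 0],
        "S": hsv[rows, cols, 1],
        "V": hsv[rows, cols, 2],
        "L": lab[rows, cols, 0],
        "a": lab[rows, cols, 1],
        "b": lab[rows, cols, 2],
    }
    df = pd.DataFrame(data, columns=FEATURE_TABLE_COLUMNS)
    if annotation is not None:
        df["label"] = annotation.mask[rows, cols].astype(np.int64)
    return df
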