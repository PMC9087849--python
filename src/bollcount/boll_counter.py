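"""From per-pixel predictions to a boll count.

Predicted cotton pixels are rasterized to a binary mask, denoised with a
morphological erosion (3x3 elliptic structuring element, i.e. the 5-pixel
cross) followed by a dilation (5x5 rectangular), and counted as 8-connected
components: one component = one boll.  Touching or near-touching bolls merge
under the dilation and are counted once — a documented under-count mode in
high-density canopies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.color import label2rgb
from PIL import Image

from . import color_features
from .pixel_classifier import TrainedPixelClassifier
from .types import BackgroundMask, PlotImage, ValidationError


@dataclass(frozen=True)
class StructuringElement:
    """A binary morphology footprint: 'elliptic' or 'rectangular'."""

    shape: str
    size: tuple[int, int]

    def __post_init__(self) -> None:
        r, c = self.size
        if r < 1 or c < 1 or r % 2 == 0 or c % 2 == 0:
            raise ValidationError("structuring-element sides must be odd positive")
        if self.shape not in ("elliptic", "rectangular"):
            raise ValidationError(f"unknown structuring-element shape {self.shape!r}")

    @property
    def footprint(self) -> np.ndarray:
        rows, cols = self.size
        if self.shape == "rectangular":
            return np.ones((rows, cols), dtype=bool)
        # inscribed discrete ellipse; at 3x3 this is the 5-pixel cross
        ry, cx = (rows - 1) / 2, (cols - 1) / 2
        rr, cc = np.mgrid[-ry : ry + 1, -cx : cx + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            inside = (rr / max(ry, 0.5)) ** 2 + (cc / max(cx, 0.5)) ** 2 <= 1.0
        inside[int(ry), int(cx)] = True
        return inside


ERODE_DEFAULT = StructuringElement("elliptic", (3, 3))
DILATE_DEFAULT = StructuringElement("rectangular", (5, 5))


@dataclass
class BollCountResult:
    """Post-processed mask, component label map, and the boll count."""

    plot_id: str
    binary_mask: np.ndarray  # H x W, {0,1} after morphology
    label_map: np.ndarray  # H x W ints, 0 = background
    boll_count: int
    components: list[tuple[int, int, tuple[float, float]]]  # (label, area, centroid)
    stage_counts: dict[str, int] = field(default_factory=dict)


def labels_to_mask(
    rows: Sequence[int],
    cols: Sequence[int],
    labels: Sequence[int],
    shape: tuple[int, int],
) -> np.ndarray:
    """Rasterize per-pixel predictions to a binary mask.

    Mask is 1 exactly at coordinates predicted cotton; duplicates or
    out-of-bounds coordinates are contract violations.
    """
    rows = np.asarray(rows, dtype=np.int64)
    cols = np.asarray(cols, dtype=np.int64)
    labels = np.asarray(labels)
    H, W = shape
    if rows.size and (
        rows.min() < 0 or rows.max() >= H or cols.min() < 0 or cols.max() >= W
    ):
        raise ValidationError("pixel coordinate out of bounds")
    flat = rows * W + cols
    if np.unique(flat).size != flat.size:
        raise ValidationError("duplicate (row, col) coordinates")
    mask = np.zeros(shape, dtype=np.uint8)
    mask[rows[labels == 1], cols[labels == 1]] = 1
    return mask


def morph_postprocess(
    mask: np.ndarray,
    erode_se: StructuringElement = ERODE_DEFAULT,
    dilate_se: StructuringElement = DILATE_DEFAULT,
) -> np.ndarray:
    """Erosion then dilation to remove isolated misclassified pixels.

    Outside-image pixels count as background for the erosion and do not
    contribute to the dilation.
    """
    m = np.asarray(mask) != 0
    eroded = ndimage.binary_erosion(m, structure=erode_se.footprint, border_value=0)
    dilated = ndimage.binary_dilation(eroded, structure=dilate_se.footprint, border_value=0)
    return dilated.astype(np.uint8)


def count_components(
    mask: np.ndarray, min_area: int = 1, plot_id: str = ""
) -> BollCountResult:
    """Label 8-connected (Moore-neighborhood) components and count them.

    Labels are renumbered by first raster-scan encounter; components smaller
    than ``min_area`` pixels are dropped.
    """
    m = np.asarray(mask) != 0
    raw_labels, n = ndimage.label(m, structure=np.ones((3, 3), dtype=bool))
    label_map = np.zeros_like(raw_labels)
    components = []
    if n:
        areas = np.bincount(raw_labels.ravel())[1:]
        # order by first raster-scan encounter
        flat = raw_labels.ravel()
        first_idx = np.full(n + 1, flat.size, dtype=np.int64)
        nz = np.nonzero(flat)[0]
        np.minimum.at(first_idx, flat[nz], nz)
        order = np.argsort(first_idx[1:], kind="stable") + 1
        centroids = ndimage.center_of_mass(m, raw_labels, order)
        new_label = 0
        for old, cen in zip(order, centroids):
            if areas[old - 1] < min_area:
                continue
            new_label += 1
            label_map[raw_labels == old] = new_label
            components.append(
                (new_label, int(areas[old - 1]), (float(cen[0]), float(cen[1])))
            )
    binary = (label_map > 0).astype(np.uint8)
    return BollCountResult(
        plot_id=plot_id,
        binary_mask=binary,
        label_map=label_map,
        boll_count=len(components),
        components=components,
    )


def estimate_plot_yield(
    image: PlotImage,
    classifier: TrainedPixelClassifier,
    veg_threshold: float = 0.0,
    soil_threshold: float = 0.35,
    erode_se: StructuringElement = ERODE_DEFAULT,
    dilate_se: StructuringElement = DILATE_DEFAULT,
    min_area: int = 1,
) -> BollCountResult:
    """Full per-plot pipeline: background removal -> SVM -> morphology -> count."""
    bg = color_features.background_mask(image, veg_threshold, soil_threshold)
    table = color_features.extract_features(image, bg)
    labels = classifier.predict(table)
    mask = labels_to_mask(
        table["row"].to_numpy(), table["col"].to_numpy(), labels, image.shape
    )
    post = morph_postprocess(mask, erode_se, dilate_se)
    result = count_components(post, min_area=min_area, plot_id=image.plot_id)
    result.stage_counts = {
        "raw_pixels": bg.raw_pixels,
        "after_vegetation": bg.after_vegetation,
        "after_soil": bg.after_soil,
        "predicted_cotton": int(mask.sum()),
        "after_morphology": int(post.sum()),
    }
    return result


def write_counts_csv(results: Sequence[BollCountResult], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(r.plot_id, r.boll_count) for r in results],
        columns=["plot_id", "boll_count"],
    ).to_csv(path, index=False)
    return path


def write_label_map(result: BollCountResult, path: str | Path) -> Path:
    """Label map as a single-band 32-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, result.label_map.astype(np.int32))
    return path


def write_cluster_visualization(
    result: BollCountResult, path: str | Path, image: Optional[PlotImage] = None
) -> Path:
    """RGB rendering with one distinct color per component."""
    bg_img = image.pixels / 255.0 if image is not None else None
    rgb = label2rgb(result.label_map, image=bg_img, bg_label=0)
    Image.fromarray((rgb * 255).astype(np.uint8)).save(Path(path))
    return Path(path)
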