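"""Reading and writing plot imagery, masks, boundaries and ground truth.

Rasters are GeoTIFF/TIFF (via tifffile, with ModelPixelScale/ModelTiepoint
georeferencing tags when present) or PNG/JPEG (via Pillow, pixel coordinates
only).  Annotation masks are single-band TIFFs.  Plot boundaries come from a
GeoJSON FeatureCollection whose features carry a ``plot_id`` property, and
ground truth from a UTF-8 CSV with columns plot_id, genotype, boll_count.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from skimage.draw import polygon2mask

from .types import (
    AnnotationMask,
    FormatError,
    GroundTruthRecord,
    PlotBoundary,
    PlotImage,
    ValidationError,
)

_TIFF_SUFFIXES = {".tif", ".tiff"}

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922


def _geotransform_from_tags(page) -> Optional[tuple[float, ...]]:
    tags = page.tags
    if _MODEL_PIXEL_SCALE in tags and _MODEL_TIEPOINT in tags:
        sx, sy = tags[_MODEL_PIXEL_SCALE].value[:2]
        i, j, _k, x, y, _z = tags[_MODEL_TIEPOINT].value[:6]
        # tiepoint maps raster (i=col, j=row) to world (x, y); y axis points down
        return (x - i * sx, sx, 0.0, y + j * sy, 0.0, -sy)
    return None


def read_plot_image(path: str | Path, plot_id: Optional[str] = None) -> PlotImage:
    """Read a >=3-band raster as an RGB :class:`PlotImage`.

    Extra bands (e.g. alpha) are dropped.  The GeoTIFF geotransform is
    preserved when the file carries georeferencing tags.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pid = plot_id if plot_id is not None else path.stem
    geotransform = None
    if path.suffix.lower() in _TIFF_SUFFIXES:
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            geotransform = _geotransform_from_tags(tif.pages[0])
    else:
        arr = np.asarray(Image.open(path).convert("RGBA"))
    if arr.ndim == 3 and arr.shape[0] in (3, 4) and arr.shape[2] not in (3, 4):
        arr = np.moveaxis(arr, 0, -1)  # band-major TIFFs
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise FormatError(f"{path} has fewer than 3 bands")
    return PlotImage(pid, arr[:, :, :3].astype(np.uint8), geotransform=geotransform)


def write_plot_image(image: PlotImage, path: str | Path) -> Path:
    """Write an image as PNG/JPEG or (Geo)TIFF depending on the suffix."""
    path = Path(path)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        extratags = []
        if image.geotransform is not None:
            x0, sx, _b, y0, _d, sy = image.geotransform
            extratags = [
                (_MODEL_PIXEL_SCALE, "d", 3, (sx, abs(sy), 0.0)),
                (_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
            ]
        tifffile.imwrite(path, image.pixels, photometric="rgb", extratags=extratags)
    else:
        Image.fromarray(image.pixels).save(path)
    return path


def read_mask(path: str | Path, plot_id: Optional[str] = None) -> AnnotationMask:
    """Read a single-band raster as a binary mask (nonzero -> 1)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path) if path.suffix.lower() in _TIFF_SUFFIXES else np.asarray(
        Image.open(path)
    )
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    pid = plot_id if plot_id is not None else path.stem
    return AnnotationMask(pid, arr)


def write_mask(mask: AnnotationMask, path: str | Path, scale255: bool = True) -> Path:
    """Write a binary mask as a single-band TIFF (foreground stored as 255)."""
    path = Path(path)
    out = mask.mask * (255 if scale255 else 1)
    tifffile.imwrite(path, out.astype(np.uint8))
    return path


def read_boundaries(path: str | Path) -> list[PlotBoundary]:
    """Parse a GeoJSON FeatureCollection of plot polygons."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    out = []
    for feat in gj.get("features", []):
        props = feat.get("properties") or {}
        if "plot_id" not in props:
            raise ValidationError("GeoJSON feature missing 'plot_id' property")
        geom = feat["geometry"]
        if geom["type"] != "Polygon":
            raise FormatError(f"unsupported geometry type {geom['type']}")
        ring = [tuple(pt) for pt in geom["coordinates"][0]]
        out.append(PlotBoundary(str(props["plot_id"]), ring))
    return out


def clip_plots(
    orthomosaic: PlotImage, boundaries: Iterable[PlotBoundary]
) -> list[Optional[PlotImage]]:
    """Clip one image per boundary from an orthomosaic.

    The output extent is the axis-aligned bounding box of the polygon in
    pixel space; pixels outside the polygon are zero-filled.  World
    coordinates are converted via the inverse geotransform when present.
    A polygon wholly outside the raster yields ``None`` with a warning.
    """
    H, W = orthomosaic.shape
    out: list[Optional[PlotImage]] = []
    for b in boundaries:
        # (x, y) -> fractional (row, col)
        rc = np.array([orthomosaic.world_to_pixel(x, y) for x, y in b.vertices])
        r0 = int(np.floor(rc[:, 0].min()))
        r1 = int(np.ceil(rc[:, 0].max()))
        c0 = int(np.floor(rc[:, 1].min()))
        c1 = int(np.ceil(rc[:, 1].max()))
        if r1 <= 0 or c1 <= 0 or r0 >= H or c0 >= W:
            warnings.warn(f"plot {b.plot_id}: boundary outside raster extent")
            out.append(None)
            continue
        r0c, r1c = max(r0, 0), min(r1, H)
        c0c, c1c = max(c0, 0), min(c1, W)
        shape = (r1c - r0c, c1c - c0c)
        local = rc - np.array([r0c, c0c])
        inside = polygon2mask(shape, local)
        sub = orthomosaic.pixels[r0c:r1c, c0c:c1c].copy()
        sub[~inside] = 0
        geo = None
        if orthomosaic.geotransform is not None:
            x0, a, bb, y0, d, e = orthomosaic.geotransform
            geo = (x0 + c0c * a + r0c * bb, a, bb, y0 + c0c * d + r0c * e, d, e)
        out.append(PlotImage(b.plot_id, sub, geotransform=geo, crs=orthomosaic.crs))
    return out


def read_ground_truth(path: str | Path) -> list[GroundTruthRecord]:
    """Read and validate the per-plot ground-truth CSV."""
    df = pd.read_csv(path, dtype={"plot_id": str, "genotype": str})
    required = {"plot_id", "genotype", "boll_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ground-truth CSV missing columns: {sorted(missing)}")
    if df["plot_id"].duplicated().any():
        dups = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValidationError(f"duplicate plot_id values: {dups}")
    return [
        GroundTruthRecord(r.plot_id, r.genotype, int(r.boll_count))
        for r in df.itertuples(index=False)
    ]


def write_ground_truth(records: Iterable[GroundTruthRecord], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(r.plot_id, r.genotype, r.boll_count) for r in records],
        columns=["plot_id", "genotype", "boll_count"],
    ).to_csv(path, index=False)
    return path
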