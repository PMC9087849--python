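"""Core domain containers shared across the pipeline.

Coordinate convention throughout the package: 0-based ``(row, col)`` indexing,
row-major, with row 0 at the top of the image.  Geotransforms follow the GDAL
6-number affine convention ``(x0, dx_col, dx_row, y0, dy_col, dy_row)`` so that

    x = x0 + col * dx_col + row * dx_row
    y = y0 + col * dy_col + row * dy_row
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


class ValidationError(ValueError):
    """Raised when an input violates a documented contract."""


class FormatError(ValueError):
    """Raised when a file has the wrong band count or layout."""


@dataclass
class PlotImage:
    """One plot's 8-bit RGB raster plus identity/geo metadata."""

    plot_id: str
    pixels: np.ndarray  # H x W x 3, uint8, channel order R,G,B
    geotransform: Optional[tuple[float, float, float, float, float, float]] = None
    crs: Optional[str] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"PlotImage requires an HxWx3 array, got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("PlotImage must have H >= 1 and W >= 1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValidationError("pixel intensities must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def world_to_pixel(self, x: float, y: float) -> tuple[float, float]:
        """Invert the affine geotransform; returns fractional (row, col)."""
        if self.geotransform is None:
            return y, x
        x0, a, b, y0, d, e = self.geotransform
        det = a * e - b * d
        if det == 0:
            raise ValidationError("geotransform is singular")
        col = (e * (x - x0) - b * (y - y0)) / det
        row = (-d * (x - x0) + a * (y - y0)) / det
        return row, col


@dataclass
class AnnotationMask:
    """Binary per-pixel class truth: 1 = cotton, 0 = non-cotton."""

    plot_id: str
    mask: np.ndarray  # H x W, values in {0, 1}

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2:
            raise FormatError(f"mask must be single-channel, got shape {m.shape}")
        self.mask = (m != 0).astype(np.uint8)


@dataclass(frozen=True)
class GroundTruthRecord:
    plot_id: str
    genotype: str
    boll_count: int

    def __post_init__(self) -> None:
        if self.boll_count < 0:
            raise ValidationError(
                f"boll_count must be >= 0, got {self.boll_count} for {self.plot_id}"
            )


@dataclass
class PlotBoundary:
    """Closed polygon delimiting one plot, in world or pixel coordinates.

    Vertices are (x, y) pairs; the ring is normalized so first == last.
    """

    plot_id: str
    polygon: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        poly = [tuple(map(float, p)) for p in self.polygon]
        if len(poly) >= 1 and poly[0] == poly[-1]:
            ring = poly
        else:
            ring = poly + poly[:1]
        if len(ring) < 4:  # 3 distinct vertices + closing point
            raise ValidationError("polygon needs at least 3 vertices")
        self.polygon = ring

    @property
    def vertices(self) -> np.ndarray:
        """Open ring (closing vertex dropped) as an (n, 2) array of (x, y)."""
        return np.asarray(self.polygon[:-1], dtype=float)


@dataclass
class BackgroundMask:
    """Which pixels survive the two-stage color-index background removal."""

    retained: np.ndarray  # H x W, 1 = kept for classification
    raw_pixels: int
    after_vegetation: int
    after_soil: int

    def __post_init__(self) -> None:
        self.retained = (np.asarray(self.retained) != 0).astype(np.uint8)
        if not (self.after_soil <= self.after_vegetation <= self.raw_pixels):
            raise ValidationError(
                "stage counts must be monotone non-increasing: "
                f"{self.raw_pixels} -> {self.after_vegetation} -> {self.after_soil}"
            )
        if int(self.retained.sum()) != self.after_soil:
            raise ValidationError("retained pixel sum must equal after_soil count")

    @property
    def vegetation_retention_pct(self) -> float:
        """Percent of raw pixels surviving the vegetation-removal stage."""
        return 100.0 * self.after_vegetation / self.raw_pixels

    @property
    def overall_retention_pct(self) -> float:
        """Percent of raw pixels surviving both removal stages."""
        return 100.0 * self.after_soil / self.raw_pixels


def reduction_report(raw: int, after_vegetation: int, after_soil: int) -> str:
    """Human-readable per-stage pixel reduction summary.

    Percentages are printed to two decimals, e.g. counts
    523092 -> 231447 -> 34212 report 44.25% and 6.54%.
    """
    veg = 100.0 * after_vegetation / raw
    overall = 100.0 * after_soil / raw
    return (
        f"raw pixels: {raw}; after vegetation removal: {after_vegetation} "
        f"({veg:.2f}%); after soil removal: {after_soil} ({overall:.2f}%)"
    )
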