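"""Synthetic plot scenes with exact per-pixel class truth and boll counts.

A scene emulates the elements of an aerial cotton-plot image at desk scale:

* soil — a reddish-brown base (CIELAB L* 45-62, a* 10-16, b* 12-24) with
  Gaussian texture noise; scores low on the soil index and is removed by
  background masking;
* vegetation — green elliptical blobs (high G channel) with a strongly
  positive excess-green index, removed at the vegetation stage;
* wood — light-brown linear segments (L* 62-75, a* 6-12, b* 18-28) that
  straddle the soil-index threshold: the deliberate false-positive confuser
  the classifier must reject;
* cotton bolls — bright, low-chroma elliptical disks (center L* 85-98,
  |a*|, |b*| small) with a linear radial lightness falloff of 25 L* units to
  the rim, so boll edges sink below the soil-index threshold and only cores
  are retained — the deliberate partial-detection mechanism.

Boll placement is rejection sampling with a per-boll retry cap; with
``min_separation`` > 0 the rendered disks are pairwise disjoint (center
distance >= r_i + r_j + min_separation).  Everything is reproducible from
the seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.color import lab2rgb

from . import imagery_io
from .types import AnnotationMask, PlotImage, ValidationError

CLASS_SOIL, CLASS_VEGETATION, CLASS_WOOD, CLASS_COTTON = 0, 1, 2, 3
CLASS_NAMES = {0: "soil", 1: "vegetation", 2: "wood", 3: "cotton"}


class PlacementError(RuntimeError):
    """Raised when bolls cannot be placed at the requested separation."""


@dataclass
class SceneConfig:
    """Parameters of one synthetic plot scene."""

    height: int = 256
    width: int = 256
    n_bolls: int = 50
    boll_radius_range: tuple[float, float] = (2.5, 4.0)
    min_separation: float = 4.0  # gap between disk boundaries, px
    vegetation_fraction: float = 0.15
    wood_fraction: float = 0.04
    illumination_gradient: float = 0.0  # relative left-right lightness ramp
    noise_sd: float = 2.0  # 8-bit intensity units
    seed: int = 0
    max_retries: int = 10_000  # per-boll rejection-sampling cap

    def __post_init__(self) -> None:
        if self.n_bolls < 0:
            raise ValidationError("n_bolls must be >= 0")
        if self.min_separation < 0:
            raise ValidationError("min_separation must be >= 0")
        if self.vegetation_fraction + self.wood_fraction > 1:
            raise ValidationError("class fractions must sum to <= 1")


@dataclass
class SyntheticScene:
    image: PlotImage
    mask: AnnotationMask  # true cotton pixels
    boll_truth: list[tuple[tuple[float, float], float]]  # ((row, col), radius)
    true_count: int
    class_map: np.ndarray  # H x W in {soil, vegetation, wood, cotton}
    config: SceneConfig


def _place_bolls(config: SceneConfig, rng: np.random.Generator):
    rmin, rmax = config.boll_radius_range
    placed: list[tuple[float, float, float]] = []  # row, col, radius
    for _ in range(config.n_bolls):
        for attempt in range(config.max_retries):
            r = rng.uniform(rmin, rmax)
            row = rng.uniform(r + 1, config.height - r - 1)
            col = rng.uniform(r + 1, config.width - r - 1)
            ok = all(
                (row - pr) ** 2 + (col - pc) ** 2
                >= (r + prad + config.min_separation) ** 2
                for pr, pc, prad in placed
            )
            if ok:
                placed.append((row, col, r))
                break
        else:
            raise PlacementError(
                f"could not place boll {len(placed) + 1}/{config.n_bolls} "
                f"after {config.max_retries} retries"
            )
    return placed


def _paint_blobs(
    class_map: np.ndarray,
    target_fraction: float,
    class_id: int,
    axes_range: tuple[float, float],
    rng: np.random.Generator,
) -> None:
    """Add random ellipses of one class until its pixel fraction is reached."""
    H, W = class_map.shape
    target = int(target_fraction * H * W)
    rr, cc = np.mgrid[0:H, 0:W]
    guard = 0
    while np.sum(class_map == class_id) < target and guard < 1000:
        guard += 1
        cy, cx = rng.uniform(0, H), rng.uniform(0, W)
        ay = rng.uniform(*axes_range)
        ax = rng.uniform(*axes_range)
        theta = rng.uniform(0, np.pi)
        dy, dx = rr - cy, cc - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / ay) ** 2 + (v / ax) ** 2 <= 1.0
        class_map[inside & (class_map == CLASS_SOIL)] = class_id


def _paint_segments(
    class_map: np.ndarray, target_fraction: float, rng: np.random.Generator
) -> None:
    """Add thin line segments (wood) until the pixel fraction is reached."""
    H, W = class_map.shape
    target = int(target_fraction * H * W)
    rr, cc = np.mgrid[0:H, 0:W]
    guard = 0
    while np.sum(class_map == CLASS_WOOD) < target and guard < 2000:
        guard += 1
        y0, x0 = rng.uniform(0, H), rng.uniform(0, W)
        length = rng.uniform(10, 0.4 * max(H, W))
        theta = rng.uniform(0, np.pi)
        half_t = rng.uniform(0.6, 1.6)
        dy, dx = rr - y0, cc - x0
        along = dy * np.cos(theta) + dx * np.sin(theta)
        across = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (np.abs(across) <= half_t) & (along >= 0) & (along <= length)
        class_map[inside & (class_map == CLASS_SOIL)] = CLASS_WOOD


def generate_scene(config: SceneConfig) -> SyntheticScene:
    """Render one scene; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    H, W = config.height, config.width
    class_map = np.full((H, W), CLASS_SOIL, dtype=np.uint8)

    bolls = _place_bolls(config, rng)
    _paint_blobs(
        class_map, config.vegetation_fraction, CLASS_VEGETATION, (4.0, 14.0), rng
    )
    _paint_segments(class_map, config.wood_fraction, rng)

    # soil base in CIELAB with mild texture; texture scales with noise_sd so
    # a zero-noise scene renders exactly repeating soil colors
    tex = config.noise_sd / 2.0
    lab = np.empty((H, W, 3))
    lab[:, :, 0] = np.clip(rng.normal(54, 4 * tex, (H, W)), 45, 62)
    lab[:, :, 1] = np.clip(rng.normal(13, 1.5 * tex, (H, W)), 10, 16)
    lab[:, :, 2] = np.clip(rng.normal(18, 3 * tex, (H, W)), 12, 24)

    wood = class_map == CLASS_WOOD
    n_wood = int(wood.sum())
    lab[wood, 0] = rng.uniform(62, 75, n_wood)
    lab[wood, 1] = rng.uniform(6, 12, n_wood)
    lab[wood, 2] = rng.uniform(18, 28, n_wood)

    # bolls: radial lightness falloff from center L* to center-25 at the rim
    rr, cc = np.mgrid[0:H, 0:W]
    for row, col, radius in bolls:
        center_L = rng.uniform(85, 98)
        a_star = rng.uniform(-3, 1)
        b_star = rng.uniform(-1, 5)
        dist = np.sqrt((rr - row) ** 2 + (cc - col) ** 2)
        inside = dist <= radius
        class_map[inside] = CLASS_COTTON
        lab[inside, 0] = center_L - 25.0 * (dist[inside] / radius)
        lab[inside, 1] = a_star
        lab[inside, 2] = b_star

    rgb = lab2rgb(lab)
    veg = class_map == CLASS_VEGETATION
    n_veg = int(veg.sum())
    # R and B bounded fractions of G keep the excess-green index positive
    veg_g = rng.uniform(100, 180, n_veg)
    rgb[veg, 0] = veg_g * rng.uniform(0.25, 0.55, n_veg) / 255.0
    rgb[veg, 1] = veg_g / 255.0
    rgb[veg, 2] = veg_g * rng.uniform(0.20, 0.55, n_veg) / 255.0

    if config.illumination_gradient:
        ramp = 1.0 + config.illumination_gradient * (
            np.arange(W) / max(W - 1, 1) - 0.5
        )
        rgb = rgb * ramp[None, :, None]

    out = rgb * 255.0
    if config.noise_sd > 0:
        out = out + rng.normal(0.0, config.noise_sd, out.shape)
    pixels = np.clip(np.round(out), 0, 255).astype(np.uint8)

    plot_id = f"synthetic-{config.seed}"
    image = PlotImage(plot_id, pixels)
    mask = AnnotationMask(plot_id, (class_map == CLASS_COTTON).astype(np.uint8))
    return SyntheticScene(
        image=image,
        mask=mask,
        boll_truth=[((row, col), radius) for row, col, radius in bolls],
        true_count=len(bolls),
        class_map=class_map,
        config=config,
    )


def scene_to_training_fixture(
    scene: SyntheticScene, out_dir: str | Path
) -> tuple[Path, Path, Path]:
    """Write PNG image + TIF mask + JSON truth sidecar for one scene."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pid = scene.image.plot_id
    img_path = imagery_io.write_plot_image(scene.image, out_dir / f"{pid}.png")
    mask_path = imagery_io.write_mask(scene.mask, out_dir / f"{pid}_mask.tif")
    truth = {
        "plot_id": pid,
        "true_count": scene.true_count,
        "bolls": [
            {"center_row": c[0], "center_col": c[1], "radius": r}
            for c, r in scene.boll_truth
        ],
        "config": dataclasses.asdict(scene.config),
    }
    truth_path = out_dir / f"{pid}_truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return img_path, mask_path, truth_path
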