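"""Pipeline-wide configuration, loadable from a single YAML file."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .boll_counter import DILATE_DEFAULT, ERODE_DEFAULT, StructuringElement
from .pixel_classifier import ClassifierConfig
from .types import ValidationError


@dataclass
class PipelineConfig:
    """Every tunable of the counting pipeline with its default.

    Defaults follow the reference protocol where it states a value (C = 1.0,
    gamma = "scale", 4:1 split, 3x3 elliptic erosion, 5x5 rectangular
    dilation, 8-connectivity, alpha = 0.05); the two background-removal
    thresholds are calibration choices documented in the methods note.
    """

    veg_threshold: float = 0.0
    soil_threshold: float = 0.35
    se_erode: StructuringElement = ERODE_DEFAULT
    se_dilate: StructuringElement = DILATE_DEFAULT
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    min_area: int = 1
    seed: int = 0
    alpha: float = 0.05

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return PipelineConfig.from_dict(raw)

    @staticmethod
    def from_dict(raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("se_erode", "se_dilate"):
            if key in kwargs and not isinstance(kwargs[key], StructuringElement):
                spec = kwargs[key]
                kwargs[key] = StructuringElement(spec["shape"], tuple(spec["size"]))
        if "classifier" in kwargs and not isinstance(
            kwargs["classifier"], ClassifierConfig
        ):
            c = dict(kwargs["classifier"])
            if "split_ratio" in c:
                c["split_ratio"] = tuple(c["split_ratio"])
            kwargs["classifier"] = ClassifierConfig(**c)
        return PipelineConfig(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        blob = dataclasses.asdict(self)
        path.write_text(yaml.safe_dump(blob, sort_keys=False))
        return path
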