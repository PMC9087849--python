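"""High-level orchestration shared by the CLI, examples and tests."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import boll_counter, color_features, pixel_classifier
from .config import PipelineConfig
from .pixel_classifier import ClassificationMetrics, TrainedPixelClassifier
from .types import AnnotationMask, PlotImage, ValidationError, reduction_report

log = logging.getLogger("bollcount")


@dataclass
class TrainingReport:
    classifier: TrainedPixelClassifier
    selected_features: list[str]
    feature_scores: dict[str, float]
    metrics: ClassificationMetrics
    n_train: int
    n_test: int
    reduction: str


def train_pixel_classifier(
    image: PlotImage,
    annotation: AnnotationMask,
    config: Optional[PipelineConfig] = None,
) -> TrainingReport:
    """Train the pixel classifier from one annotated plot image.

    Steps: background removal -> labeled feature extraction -> recursive
    feature elimination (keep ``selected_k`` of the 9 color channels) ->
    4:1 split -> RBF SVM fit -> test-subset metrics.
    """
    config = config or PipelineConfig()
    if annotation.mask.shape != image.shape:
        raise ValidationError(
            f"annotation shape {annotation.mask.shape} != image shape {image.shape}"
        )
    bg = color_features.background_mask(
        image, config.veg_threshold, config.soil_threshold
    )
    reduction = reduction_report(bg.raw_pixels, bg.after_vegetation, bg.after_soil)
    log.info("%s: %s", image.plot_id, reduction)

    table = color_features.extract_features(image, bg, annotation)
    if table.empty:
        raise ValidationError("no pixels retained after background removal")
    cconf = config.classifier
    train_tbl, test_tbl = pixel_classifier.split_dataset(
        table, cconf.split_ratio, cconf.seed
    )
    selected, scores = pixel_classifier.select_features(
        train_tbl, k=cconf.selected_k, seed=cconf.seed
    )
    log.info("selected features: %s", selected)
    clf = pixel_classifier.train_svm(
        train_tbl, cconf, features=selected, n_test=len(test_tbl)
    )
    preds = clf.predict(test_tbl)
    metrics = pixel_classifier.compute_metrics(preds, test_tbl["label"].to_numpy())
    log.info(
        "test metrics: accuracy %.1f%% precision %.1f%% recall %.1f%% F1 %.1f%%",
        metrics.accuracy,
        metrics.precision,
        metrics.recall,
        metrics.f1,
    )
    return TrainingReport(
        classifier=clf,
        selected_features=selected,
        feature_scores=scores,
        metrics=metrics,
        n_train=len(train_tbl),
        n_test=len(test_tbl),
        reduction=reduction,
    )


def count_plot(
    image: PlotImage,
    classifier: TrainedPixelClassifier,
    config: Optional[PipelineConfig] = None,
) -> boll_counter.BollCountResult:
    """Run the counting pipeline on one plot image."""
    config = config or PipelineConfig()
    result = boll_counter.estimate_plot_yield(
        image,
        classifier,
        veg_threshold=config.veg_threshold,
        soil_threshold=config.soil_threshold,
        erode_se=config.se_erode,
        dilate_se=config.se_dilate,
        min_area=config.min_area,
    )
    log.info(
        "%s: stage counts %s -> boll_count %d",
        image.plot_id,
        result.stage_counts,
        result.boll_count,
    )
    return result
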