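"""SVM pixel classification: split, feature selection, training, metrics.

The classifier is trained from a single annotated plot: retained pixels are
split 4:1 into train/test, recursive feature elimination with a random-forest
importance estimator keeps the 4 most informative of the 9 color channels,
and an RBF-kernel SVM (C = 1.0, gamma = "scale") learns cotton vs non-cotton.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.svm import SVC

from .color_features import COLOR_FEATURES
from .types import ValidationError


@dataclass
class ClassifierConfig:
    """Hyperparameters of the pixel classifier."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str = "scale"  # 1 / (n_features * X.var())
    selected_k: int = 4
    split_ratio: tuple[int, int] = (4, 1)  # train : test
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be positive")
        if any(p <= 0 for p in self.split_ratio):
            raise ValidationError("split ratio parts must be positive")

    @property
    def train_fraction(self) -> float:
        a, b = self.split_ratio
        return a / (a + b)


def split_dataset(
    table: pd.DataFrame, ratio: tuple[int, int] = (4, 1), seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Shuffle and split a labeled feature table.

    Train size is ``floor(N * train_fraction)``; the split is a seeded
    unstratified uniform shuffle, disjoint and exhaustive.
    """
    if len(table) == 0:
        raise ValidationError("cannot split an empty table")
    if any(p <= 0 for p in ratio):
        raise ValidationError("split ratio parts must be positive")
    n = len(table)
    n_train = int(np.floor(n * ratio[0] / (ratio[0] + ratio[1])))
    perm = np.random.default_rng(seed).permutation(n)
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]


def select_features(
    train: pd.DataFrame,
    k: int = 4,
    seed: int = 0,
    candidates: Sequence[str] = tuple(COLOR_FEATURES),
    n_trees: int = 100,
) -> tuple[list[str], dict[str, float]]:
    """Recursive feature elimination over the 9 color channels.

    One feature is dropped per round, ranked by impurity-based importance of
    a seeded random forest, until ``k`` remain.  Returns the selected names
    ordered by final-forest importance (descending) plus their scores.
    """
    candidates = list(candidates)
    if k > len(candidates):
        raise ValidationError(f"k={k} exceeds {len(candidates)} candidate features")
    X = train[candidates].to_numpy()
    y = train["label"].to_numpy()
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if k == len(candidates):
        selected = candidates
    else:
        rfe = RFE(estimator=rf, n_features_to_select=k, step=1)
        rfe.fit(X, y)
        selected = [f for f, keep in zip(candidates, rfe.support_) if keep]
    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    final.fit(train[selected].to_numpy(), y)
    scores = dict(zip(selected, final.feature_importances_))
    ordered = sorted(selected, key=lambda f: -scores[f])
    return ordered, {f: float(scores[f]) for f in ordered}


@dataclass
class TrainedPixelClassifier:
    """A fitted SVM over the selected features, with training provenance."""

    selected_features: list[str]
    model: SVC
    config: ClassifierConfig
    n_train: int
    n_test: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Per-row labels in {0, 1}; empty input yields an empty array."""
        missing = [f for f in self.selected_features if f not in table.columns]
        if missing:
            raise ValidationError(f"table missing feature columns: {missing}")
        if len(table) == 0:
            return np.zeros(0, dtype=np.int64)
        return self.model.predict(table[self.selected_features].to_numpy()).astype(
            np.int64
        )

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if len(table) == 0:
            return np.zeros((0, 2))
        return self.model.predict_proba(table[self.selected_features].to_numpy())

    def save(self, path: str | Path) -> Path:
        """Persist as a joblib artifact with a JSON sidecar of metadata."""
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "format_version": 1,
            "selected_features": self.selected_features,
            "config": dataclasses.asdict(self.config),
            "n_train": self.n_train,
            "n_test": self.n_test,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )
        return path

    @staticmethod
    def load(path: str | Path) -> "TrainedPixelClassifier":
        return joblib.load(path)


def train_svm(
    train: pd.DataFrame,
    config: ClassifierConfig = ClassifierConfig(),
    features: Optional[Sequence[str]] = None,
    n_test: int = 0,
) -> TrainedPixelClassifier:
    """Fit the RBF SVM on the selected feature columns.

    Features default to all 9 color channels; no standardization is applied
    — the "scale" bandwidth convention absorbs feature scale.
    """
    feats = list(features) if features is not None else list(COLOR_FEATURES)
    y = train["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("training data must contain both classes")
    import warnings

    with warnings.catch_warnings():
        # SVC(probability=True) is the protocol's model; scikit-learn >=1.9
        # warns about its planned removal
        warnings.simplefilter("ignore", FutureWarning)
        svm = SVC(
            kernel=config.kernel,
            C=config.C,
            gamma=config.gamma,
            probability=True,
            random_state=config.seed,
        )
        svm.fit(train[feats].to_numpy(), y)
    return TrainedPixelClassifier(
        selected_features=feats,
        model=svm,
        config=config,
        n_train=len(train),
        n_test=n_test,
    )


def predict_pixels(
    classifier: TrainedPixelClassifier, table: pd.DataFrame
) -> np.ndarray:
    """Apply a trained classifier to a feature table; labels in {0, 1}."""
    return classifier.predict(table)


@dataclass(frozen=True)
class ClassificationMetrics:
    """Confusion-matrix counts and the derived percentage metrics.

    Percentages are in [0, 100]; a metric with a zero denominator is NaN.
    ``type1_rate`` is the share of predicted-cotton pixels that are not
    cotton (100 - precision); ``type2_rate`` is the share of true cotton
    pixels missed (100 - recall).
    """

    TP: int
    TN: int
    FP: int
    FN: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    type1_rate: float
    type2_rate: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


def metrics_from_counts(TP: int, TN: int, FP: int, FN: int) -> ClassificationMetrics:
    """Derive all six percentage metrics from confusion-matrix counts."""

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    precision = ratio(TP, TP + FP)
    recall = ratio(TP, TP + FN)
    if np.isnan(precision) or np.isnan(recall) or precision + recall == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ClassificationMetrics(
        TP=TP,
        TN=TN,
        FP=FP,
        FN=FN,
        accuracy=ratio(TP + TN, TP + TN + FP + FN),
        precision=precision,
        recall=recall,
        f1=f1,
        type1_rate=ratio(FP, TP + FP),
        type2_rate=ratio(FN, TP + FN),
    )


def compute_metrics(
    predicted: Sequence[int], truth: Sequence[int]
) -> ClassificationMetrics:
    """Confusion-matrix metrics for binary labels (1 = cotton)."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValidationError(
            f"length mismatch: predicted {pred.shape} vs truth {true.shape}"
        )
    if pred.size == 0:
        raise ValidationError("cannot compute metrics on empty label lists")
    TP = int(np.sum((pred == 1) & (true == 1)))
    TN = int(np.sum((pred == 0) & (true == 0)))
    FP = int(np.sum((pred == 1) & (true == 0)))
    FN = int(np.sum((pred == 0) & (true == 1)))
    return metrics_from_counts(TP, TN, FP, FN)
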