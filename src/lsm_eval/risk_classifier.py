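"""Larval-risk classification of waterbodies from categorical features.

A gradient-boosted decision-tree ensemble predicts the probability that
a mapped waterbody harbors mosquito larvae from six categorical
attributes (waterbody type, origin, area size class, vegetation inside
and around, visual turbidity). A fixed decision threshold (default 0.5)
converts the probability into a high/low risk label; high-risk sites
are the ones larvicided in the drone/AI-assisted workflow.

Because missing a productive habitat is costlier than overtreating an
unproductive one, model selection is recall-oriented: the tuner
maximizes cross-validated recall subject to a configurable precision
floor.

The backend is scikit-learn's histogram gradient boosting with native
categorical splits; any boosted-tree ensemble honoring the config
surface (iteration cap, depth cap, early stopping, seed) would do.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold

from .core_io import (
    FEATURE_LEVELS,
    RecordValidationError,
    RiskLabel,
    WaterbodyFeatures,
)
from .inference_stats import confusion_metrics

__all__ = [
    "ClassifierConfig",
    "CVMetrics",
    "FeatureImportanceReport",
    "LarvalRiskModel",
    "features_to_frame",
    "train",
    "predict_risk",
    "cross_validate",
    "feature_importance",
    "field_validation",
    "tune_recall_first",
]

FEATURE_NAMES = tuple(FEATURE_LEVELS)


@dataclass(frozen=True)
class ClassifierConfig:
    """Training configuration (defaults follow the field deployment:
    up to 1000 boosting iterations, tree depth capped at 10, early
    stopping on an internal validation split, 0.5 decision threshold,
    stratified 5-fold cross-validation)."""

    max_iterations: int = 1000
    max_tree_depth: int = 10
    early_stopping: bool = True
    decision_threshold: float = 0.5
    cv_folds: int = 5
    random_seed: int = 0
    validation_fraction: float = 0.1  # internal early-stopping split
    early_stopping_patience: int = 50  # iterations without improvement

    def __post_init__(self):
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must lie in (0, 1)")
        if self.max_iterations < 1 or self.max_tree_depth < 1:
            raise ValueError("iteration and depth caps must be >= 1")


@dataclass(frozen=True)
class CVMetrics:
    accuracy: float
    precision: float
    recall: float
    fold_accuracy: tuple[float, ...]
    fold_precision: tuple[float, ...]
    fold_recall: tuple[float, ...]
    n_samples: int


@dataclass(frozen=True)
class FeatureImportanceReport:
    """Normalized relative feature importance (RFI), percentages
    summing to 100."""

    rfi: dict[str, float]

    def __post_init__(self):
        if any(v < 0 for v in self.rfi.values()):
            raise ValueError("importances must be non-negative")
        if abs(sum(self.rfi.values()) - 100.0) > 0.5:
            raise ValueError("RFI percentages must sum to 100")

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.rfi.items(), key=lambda kv: -kv[1])


def features_to_frame(features: Sequence[WaterbodyFeatures]) -> pd.DataFrame:
    """Waterbody features as a DataFrame of ordered categoricals."""
    frame = pd.DataFrame([vars(f) for f in features])
    for name, levels in FEATURE_LEVELS.items():
        frame[name] = pd.Categorical(frame[name], categories=list(levels))
    return frame


def _validate_levels(features: Sequence[WaterbodyFeatures]) -> None:
    for i, f in enumerate(features):
        for name, levels in FEATURE_LEVELS.items():
            v = getattr(f, name)
            if v not in levels:
                raise RecordValidationError(
                    f"row {i}: unknown level {v!r} for feature {name!r}"
                )


class LarvalRiskModel:
    """Trained boosted-tree risk model bound to its training vocabularies."""

    def __init__(self, estimator: HistGradientBoostingClassifier,
                 config: ClassifierConfig):
        self._estimator = estimator
        self.config = config

    def predict_proba(self, features: Sequence[WaterbodyFeatures]) -> np.ndarray:
        _validate_levels(features)
        frame = features_to_frame(features)
        return self._estimator.predict_proba(frame)[:, 1]

    @property
    def n_iterations_used(self) -> int:
        return self._estimator.n_iter_


def _make_estimator(config: ClassifierConfig) -> HistGradientBoostingClassifier:
    return HistGradientBoostingClassifier(
        max_iter=config.max_iterations,
        max_depth=config.max_tree_depth,
        early_stopping=config.early_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.early_stopping_patience,
        categorical_features="from_dtype",
        random_state=config.random_seed,
    )


def train(
    features: Sequence[WaterbodyFeatures],
    labels: Sequence[int],
    config: ClassifierConfig | None = None,
) -> LarvalRiskModel:
    """Fit the boosted-tree classifier; deterministic given the seed."""
    config = config or ClassifierConfig()
    features = list(features)
    labels = np.asarray(labels, dtype=int)
    if len(features) != len(labels):
        raise ValueError("features and labels differ in length")
    if len(features) < 2 * config.cv_folds:
        raise ValueError("need at least 2 * cv_folds samples")
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both risk classes")
    _validate_levels(features)
    est = _make_estimator(config)
    est.fit(features_to_frame(features), labels)
    return LarvalRiskModel(est, config)


def predict_risk(
    model: LarvalRiskModel, features: Sequence[WaterbodyFeatures]
) -> list[RiskLabel]:
    """Probabilities with thresholded high/low labels for new waterbodies."""
    probs = model.predict_proba(features)
    thr = model.config.decision_threshold
    return [RiskLabel(probability=float(p), threshold=thr) for p in probs]


def cross_validate(
    features: Sequence[WaterbodyFeatures],
    labels: Sequence[int],
    config: ClassifierConfig | None = None,
) -> CVMetrics:
    """Stratified k-fold cross-validation of accuracy/precision/recall.

    Folds preserve the class ratio; per-fold metrics come from the
    confusion counts at the configured decision threshold and the
    reported values are their unweighted fold averages.
    """
    config = config or ClassifierConfig()
    features = list(features)
    labels = np.asarray(labels, dtype=int)
    counts = np.bincount(labels, minlength=2)
    if counts.min() < config.cv_folds:
        raise ValueError(
            f"each class needs >= cv_folds={config.cv_folds} members "
            f"for stratification (got {counts.tolist()})"
        )
    _validate_levels(features)
    frame = features_to_frame(features)
    skf = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.random_seed
    )
    accs, precs, recs = [], [], []
    for train_idx, test_idx in skf.split(frame, labels):
        est = _make_estimator(config)
        est.fit(frame.iloc[train_idx], labels[train_idx])
        p = est.predict_proba(frame.iloc[test_idx])[:, 1]
        pred = (p >= config.decision_threshold).astype(int)
        truth = labels[test_idx]
        tp = int(np.sum((pred == 1) & (truth == 1)))
        fp = int(np.sum((pred == 1) & (truth == 0)))
        fn = int(np.sum((pred == 0) & (truth == 1)))
        tn = int(np.sum((pred == 0) & (truth == 0)))
        a, pr, rc = confusion_metrics(tp, fp, fn, tn)
        accs.append(a)
        precs.append(pr)
        recs.append(rc)
    return CVMetrics(
        accuracy=float(np.mean(accs)),
        precision=float(np.nanmean(precs)),
        recall=float(np.nanmean(recs)),
        fold_accuracy=tuple(accs),
        fold_precision=tuple(precs),
        fold_recall=tuple(recs),
        n_samples=len(features),
    )


def feature_importance(
    model: LarvalRiskModel,
    features: Sequence[WaterbodyFeatures],
    labels: Sequence[int],
    n_repeats: int = 10,
) -> FeatureImportanceReport:
    """Normalized relative feature importance (RFI) in percent.

    Importance is permutation importance of each feature on the supplied
    data (mean accuracy drop over ``n_repeats`` shuffles), clipped at
    zero and normalized to sum to 100.
    """
    frame = features_to_frame(list(features))
    result = permutation_importance(
        model._estimator, frame, np.asarray(labels, dtype=int),
        n_repeats=n_repeats, random_state=model.config.random_seed,
    )
    raw = np.clip(result.importances_mean, 0.0, None)
    if raw.sum() == 0:
        raise ValueError("no feature carries importance on these data")
    rfi = 100.0 * raw / raw.sum()
    return FeatureImportanceReport(rfi=dict(zip(frame.columns, map(float, rfi))))


def field_validation(
    predictions: Sequence[RiskLabel], larvae_observed: Sequence[int]
) -> dict:
    """Confusion counts and metrics of predictions against field surveys.

    Positive = larvae observed; a predicted-high label is a positive
    call. Returns tp/fp/fn/tn plus accuracy, precision, recall.
    """
    if len(predictions) != len(larvae_observed):
        raise ValueError("predictions and observations differ in length")
    if len(predictions) == 0:
        raise ValueError("nothing to validate")
    tp = fp = fn = tn = 0
    for pred, obs in zip(predictions, larvae_observed):
        if obs not in (0, 1):
            raise ValueError("larvae_observed entries must be 0/1")
        if pred.label == 1 and obs == 1:
            tp += 1
        elif pred.label == 1 and obs == 0:
            fp += 1
        elif pred.label == 0 and obs == 1:
            fn += 1
        else:
            tn += 1
    accuracy, precision, recall = confusion_metrics(tp, fp, fn, tn)
    return {
        "tp": tp, "fp": fp, "fn": fn, "tn": tn,
        "accuracy": accuracy, "precision": precision, "recall": recall,
    }


def tune_recall_first(
    features: Sequence[WaterbodyFeatures],
    labels: Sequence[int],
    config: ClassifierConfig | None = None,
    depth_grid: Sequence[int] = (4, 6, 10),
    precision_floor: float = 0.3,
) -> tuple[ClassifierConfig, CVMetrics]:
    """Recall-first model selection over a small depth grid.

    Among candidate depth settings, keep those whose cross-validated
    precision clears ``precision_floor`` and pick the one with the
    highest recall; if none clears the floor, fall back to the highest
    recall overall. Overlooking productive habitats is treated as the
    dominant cost.
    """
    config = config or ClassifierConfig()
    best: tuple[ClassifierConfig, CVMetrics] | None = None
    fallback: tuple[ClassifierConfig, CVMetrics] | None = None
    for depth in depth_grid:
        cand = replace(config, max_tree_depth=depth)
        metrics = cross_validate(features, labels, cand)
        if fallback is None or metrics.recall > fallback[1].recall:
            fallback = (cand, metrics)
        if metrics.precision >= precision_floor:
            if best is None or metrics.recall > best[1].recall:
                best = (cand, metrics)
    return best if best is not None else fallback
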