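"""Model-performance evaluation: accuracy metrics, uninformed baselines,
MCCV summaries, and the single-predictor precision-recall curve.

Two metrics matter here. Standard accuracy is the fraction of exact matches
and is the default for the milder class imbalance of the 5500 steps/day
threshold. Balanced accuracy, (recall + specificity) / 2, is the default for
the strongly imbalanced 2500 steps/day threshold: an uninformed classifier
scores 0.5 on it regardless of the class distribution, whereas its standard
accuracy baseline is p^2 + (1-p)^2 for positive-class fraction p.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .resampling import SplitPlan, derive_seeds

__all__ = [
    "MetricUndefinedError",
    "balanced_accuracy",
    "standard_accuracy",
    "get_metric",
    "uninformed_baseline",
    "PerformanceSummary",
    "evaluate_models",
    "PRCurve",
    "precision_recall_curve",
]


class MetricUndefinedError(ValueError):
    """Raised when a metric is undefined on a fold (a class is absent)."""


def standard_accuracy(y_true, y_pred) -> float:
    """Fraction of exact matches."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("labels are empty")
    return float(np.mean(y_true == y_pred))


def balanced_accuracy(y_true, y_pred) -> float:
    """(recall + specificity) / 2, i.e. mean of the two per-class recalls.

    Undefined when a class is absent from ``y_true``: raises
    ``MetricUndefinedError`` so the caller can flag and exclude the fold
    rather than silently propagate a NaN.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    pos = y_true == 1
    neg = y_true == 0
    if not pos.any() or not neg.any():
        raise MetricUndefinedError("balanced accuracy undefined: a class is absent")
    recall = float(np.mean(y_pred[pos] == 1))
    specificity = float(np.mean(y_pred[neg] == 0))
    return (recall + specificity) / 2.0


_METRICS: dict[str, Callable] = {
    "standard_accuracy": standard_accuracy,
    "balanced_accuracy": balanced_accuracy,
}


def get_metric(metric) -> Callable:
    if callable(metric):
        return metric
    try:
        return _METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; expected one of {sorted(_METRICS)}"
        ) from None


def uninformed_baseline(metric: str, positive_fraction: float) -> float:
    """Expected score of a classifier guessing labels at the class frequencies.

    Standard accuracy: p^2 + (1-p)^2. Balanced accuracy: 0.5 for any p.
    """
    p = positive_fraction
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"positive fraction must be in [0,1], got {p}")
    if metric == "standard_accuracy":
        return p * p + (1.0 - p) * (1.0 - p)
    if metric == "balanced_accuracy":
        return 0.5
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class PerformanceSummary:
    """Per-split MCCV scores for one algorithm/feature-set pair."""

    algorithm: str
    metric: str
    feature_set: str
    scores: tuple[float, ...]
    class_weight: str | None = None
    n_flagged_folds: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0

    @property
    def min(self) -> float:
        return float(np.min(self.scores))

    @property
    def max(self) -> float:
        return float(np.max(self.scores))


def _mccv_scores(
    make_clf: Callable[[int], object],
    X: np.ndarray,
    y: np.ndarray,
    plan: SplitPlan,
    metric_fn: Callable,
    seeds: np.ndarray,
) -> tuple[list[float], int]:
    """Fit/score over every split; returns scores and the flagged-fold count."""
    scores: list[float] = []
    flagged = 0
    for i, (train, test) in enumerate(plan):
        clf = make_clf(int(seeds[i]))
        clf.fit(X[train], y[train])
        try:
            scores.append(metric_fn(y[test], clf.predict(X[test])))
        except MetricUndefinedError:
            flagged += 1
    return scores, flagged


def evaluate_models(
    table,
    labels,
    feature_sets: Mapping[str, Sequence[str]],
    algorithms,
    plan: SplitPlan,
    metric="standard_accuracy",
    class_weight_grid: Sequence | None = None,
    seed: int = 0,
) -> dict[tuple[str, str], PerformanceSummary]:
    """MCCV performance per algorithm x feature set, optionally tuning class weight.

    ``feature_sets`` maps a label (e.g. ``all_features`` / ``selected_features``)
    to a feature list. When ``class_weight_grid`` is given (typically
    ``(None, "balanced")``), each candidate weighting is evaluated over the
    full plan and the reported summary is the grid winner by mean metric.
    """
    from .stage2 import make_classifier  # deferred: avoids a module cycle

    metric_name = metric if isinstance(metric, str) else getattr(metric, "__name__", "custom")
    metric_fn = get_metric(metric)
    y = np.asarray(labels)
    out: dict[tuple[str, str], PerformanceSummary] = {}
    for algo in algorithms:
        algo_tag = zlib.crc32(algo.family.encode()) % 100_000
        seeds = derive_seeds((seed + algo_tag) & 0x7FFFFFFF, plan.K)
        for fs_label, features in feature_sets.items():
            if len(features) == 0:
                raise ValueError(f"feature set {fs_label!r} is empty")
            X = table.data[list(features)].to_numpy()
            candidates = class_weight_grid if class_weight_grid else (algo.class_weight,)
            best = None
            for cw in candidates:
                scores, flagged = _mccv_scores(
                    lambda s, cw=cw: make_classifier(algo, split_seed=s, class_weight=cw),
                    X, y, plan, metric_fn, seeds,
                )
                summary = PerformanceSummary(
                    algorithm=algo.family,
                    metric=metric_name,
                    feature_set=fs_label,
                    scores=tuple(scores),
                    class_weight=cw,
                    n_flagged_folds=flagged,
                )
                if best is None or summary.mean > best.mean:
                    best = summary
            out[(algo.family, fs_label)] = best
    return out


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall sweep over the unique thresholds of one predictor."""

    thresholds: np.ndarray = field(repr=False)
    precision: np.ndarray = field(repr=False)
    recall: np.ndarray = field(repr=False)
    auc: float = 0.0
    no_skill: float = 0.0


def precision_recall_curve(values, labels) -> PRCurve:
    """PR curve for a single continuous predictor of a binary label.

    Higher values must indicate the positive class (negate the predictor for
    protective measures such as walking endurance). The area is the average
    precision; the no-skill line is the positive prevalence.
    """
    y = np.asarray(labels)
    v = np.asarray(values, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    precision, recall, thresholds = skm.precision_recall_curve(y, v)
    return PRCurve(
        thresholds=thresholds,
        precision=precision,
        recall=recall,
        auc=float(skm.average_precision_score(y, v)),
        no_skill=float(np.mean(y == 1)),
    )
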