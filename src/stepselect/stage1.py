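"""Stage 1: dimensionality reduction by bootstrap-screened lasso coefficients.

Two L1-regularized linear classifiers — lasso logistic regression and a
linear support-vector machine — are tuned by a refined grid search over the
regularization parameter (best mean MCCV score, two refinements around the
incumbent), then refitted over the K splits of a Monte-Carlo plan. The K
fitted coefficients of every feature form a sample; a percentile bootstrap
CI for the *median* coefficient is computed per feature and per model. A
feature is dropped only when zero lies inside the CI for *both* models;
keeping a feature requires just one model's CI to exclude zero.

Regularization strength follows the scikit-learn inverse convention: ``C``
is the inverse penalty strength, so smaller ``C`` means a stronger (sparser)
lasso. Tie-breaks in the grid search go to the smaller ``C``.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import LinearSVC

from .performance import MetricUndefinedError, get_metric
from .resampling import BootstrapCI, SplitPlan, bootstrap_ci, derive_seeds, generate_splits

__all__ = [
    "REGULARIZED_FAMILIES",
    "make_regularized",
    "TuningResult",
    "tune_regularization",
    "CoefficientSample",
    "collect_coefficients",
    "coefficient_cis",
    "SelectionResult",
    "select_features",
    "Stage1Result",
    "run_stage1",
]

REGULARIZED_FAMILIES = ("logistic", "linear_svm")


def make_regularized(
    family: str,
    C: float,
    class_weight: str | None = None,
    max_iter: int | None = None,
    scale_per_fold: bool = False,
):
    """An L1-penalized linear classifier of the given family.

    The logistic intercept is unpenalized and is never a selectable feature;
    only the slope coefficients enter the screening.
    """
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if family == "logistic":
        clf = LogisticRegression(
            l1_ratio=1.0,  # pure lasso
            solver="liblinear",
            C=C,
            class_weight=class_weight,
            max_iter=max_iter or 1000,
            random_state=0,  # liblinear shuffles internally; pin it
        )
    elif family == "linear_svm":
        clf = LinearSVC(
            penalty="l1",
            loss="squared_hinge",
            dual=False,
            C=C,
            class_weight=class_weight,
            max_iter=max_iter or 2000,
            random_state=0,
        )
    else:
        raise ValueError(f"unknown regularized family {family!r}")
    if scale_per_fold:
        return Pipeline([("scale", MinMaxScaler(clip=False)), ("clf", clf)])
    return clf


def _coef_of(clf) -> np.ndarray:
    if isinstance(clf, Pipeline):
        clf = clf.named_steps["clf"]
    return clf.coef_.ravel().copy()


def _fit_flagging_convergence(clf, X, y):
    """Fit; on ConvergenceWarning retry once with 10x iterations, then flag."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
        if not any(issubclass(w.category, ConvergenceWarning) for w in caught):
            return clf, True
    inner = clf.named_steps["clf"] if isinstance(clf, Pipeline) else clf
    inner.set_params(max_iter=inner.max_iter * 10)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        clf.fit(X, y)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    return clf, converged


@dataclass(frozen=True)
class TuningResult:
    family: str
    best_C: float
    grid_history: tuple[tuple[float, float], ...]  # (C, mean score) in eval order


def tune_regularization(
    family: str,
    table,
    labels,
    metric="balanced_accuracy",
    seed: int = 0,
    plan: SplitPlan | None = None,
    K: int = 100,
    train_fraction: float = 0.7,
    class_weight: str | None = None,
    grid_size: int = 7,
    grid_bounds: tuple[float, float] = (1e-3, 1e3),
    refinements: int = 2,
    scale_per_fold: bool = False,
) -> TuningResult:
    """Refined grid search for the regularization parameter of one lasso model.

    An initial log-spaced grid of ``grid_size`` values of ``C`` over
    ``grid_bounds`` is scored by mean MCCV metric over ``plan`` (or a fresh
    K-split plan from ``seed``); the grid is then refined twice, each
    refinement spanning one decade (log10) around the incumbent best at the
    same resolution. Ties go to the smaller ``C`` (stronger penalty), since
    the point of this stage is reduction. Raises if every candidate drives
    all coefficients to zero, naming the grid bounds.
    """
    metric_fn = get_metric(metric)
    y = np.asarray(labels)
    X = table.data.to_numpy()
    if plan is None:
        plan = generate_splits(len(y), K=K, train_fraction=train_fraction,
                               seed=int(derive_seeds(seed, 1)[0]), labels=y)

    history: list[tuple[float, float]] = []
    any_nonzero_ever = False

    def score_C(C: float) -> float:
        nonlocal any_nonzero_ever
        scores = []
        for train, test in plan:
            clf = make_regularized(family, C, class_weight, scale_per_fold=scale_per_fold)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                clf.fit(X[train], y[train])
            if np.any(_coef_of(clf) != 0.0):
                any_nonzero_ever = True
            try:
                scores.append(metric_fn(y[test], clf.predict(X[test])))
            except MetricUndefinedError:
                continue
        return float(np.mean(scores)) if scores else -np.inf

    lo, hi = np.log10(grid_bounds[0]), np.log10(grid_bounds[1])
    grid = np.logspace(lo, hi, grid_size)
    best_C, best_score = None, -np.inf
    for _round in range(refinements + 1):
        for C in sorted(grid):
            s = score_C(C)
            history.append((float(C), s))
            # ties go to the smaller C (stronger penalty, sparser model)
            if s > best_score or (s == best_score and C < best_C):
                best_C, best_score = float(C), s
        center = np.log10(best_C)
        grid = np.logspace(center - 0.5, center + 0.5, grid_size)

    if not any_nonzero_ever:
        raise ValueError(
            f"every candidate C in [{grid_bounds[0]:g}, {grid_bounds[1]:g}] "
            f"(and refinements) zeroed all coefficients for {family}"
        )
    return TuningResult(family=family, best_C=best_C, grid_history=tuple(history))


@dataclass(frozen=True)
class CoefficientSample:
    """K fitted coefficient vectors (one row per split) for one model."""

    family: str
    features: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)  # K x p
    converged: np.ndarray = field(repr=False)  # K booleans

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.converged), len(self.features)):
            raise ValueError("coefficient matrix shape mismatch")

    @property
    def n_unconverged(self) -> int:
        return int((~self.converged).sum())


def collect_coefficients(
    family: str,
    C: float,
    table,
    labels,
    plan: SplitPlan,
    class_weight: str | None = None,
    scale_per_fold: bool = False,
) -> CoefficientSample:
    """Fit the tuned model once per split (training rows only); record coefficients.

    Rows follow the plan's split order. A split whose fit fails to converge
    even after one retry with a 10x iteration cap is flagged, not dropped;
    downstream CIs use converged rows only and report the count.
    """
    y = np.asarray(labels)
    X = table.data.to_numpy()
    rows, conv = [], []
    for train, _test in plan:
        clf = make_regularized(family, C, class_weight, scale_per_fold=scale_per_fold)
        clf, ok = _fit_flagging_convergence(clf, X[train], y[train])
        rows.append(_coef_of(clf))
        conv.append(ok)
    return CoefficientSample(
        family=family,
        features=tuple(table.features),
        matrix=np.asarray(rows),
        converged=np.asarray(conv, dtype=bool),
    )


def coefficient_cis(
    sample: CoefficientSample,
    B: int = 1000,
    m: int = 100,
    level: float = 0.95,
    seed: int = 0,
) -> dict[str, BootstrapCI]:
    """Per-feature percentile bootstrap CI for the *median* coefficient."""
    use = sample.converged
    if not use.any():
        raise ValueError("no converged splits to bootstrap")
    tag = zlib.crc32(sample.family.encode()) % 100_000
    seeds = derive_seeds((seed + tag) & 0x7FFFFFFF, len(sample.features))
    return {
        feat: bootstrap_ci(sample.matrix[use, j], "median",
                           B=B, m=m, level=level, seed=int(seeds[j]))
        for j, feat in enumerate(sample.features)
    }


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the drop-iff-both screening rule."""

    retained: tuple[str, ...]
    dropped: tuple[str, ...]
    cis: dict[str, dict[str, BootstrapCI]]  # family -> feature -> CI


def select_features(
    ci_model_a: Mapping[str, BootstrapCI],
    ci_model_b: Mapping[str, BootstrapCI],
    families: tuple[str, str] = REGULARIZED_FAMILIES,
) -> SelectionResult:
    """Keep a feature if at least one model's median-coefficient CI excludes 0.

    Drop only when zero lies inside the CI for both models. Feature order of
    the first mapping is preserved in the outputs.
    """
    if set(ci_model_a) != set(ci_model_b):
        raise ValueError("the two CI maps must cover the same feature set")
    retained, dropped = [], []
    for feat, ci_a in ci_model_a.items():
        if ci_a.excludes_zero() or ci_model_b[feat].excludes_zero():
            retained.append(feat)
        else:
            dropped.append(feat)
    return SelectionResult(
        retained=tuple(retained),
        dropped=tuple(dropped),
        cis={families[0]: dict(ci_model_a), families[1]: dict(ci_model_b)},
    )


@dataclass(frozen=True)
class Stage1Result:
    selection: SelectionResult
    tuning: dict[str, TuningResult]
    samples: dict[str, CoefficientSample]


def run_stage1(
    table,
    labels,
    plan: SplitPlan,
    metric="balanced_accuracy",
    seed: int = 0,
    tune_plan: SplitPlan | None = None,
    class_weight: str | None = None,
    B: int = 1000,
    m: int = 100,
    level: float = 0.95,
    scale_per_fold: bool = False,
    **tune_kwargs,
) -> Stage1Result:
    """Tune, collect, screen: the complete reduction stage for both lasso models."""
    tuning, samples, cis = {}, {}, {}
    for family in REGULARIZED_FAMILIES:
        t = tune_regularization(
            family, table, labels, metric=metric, seed=seed,
            plan=tune_plan, class_weight=class_weight,
            scale_per_fold=scale_per_fold, **tune_kwargs,
        )
        s = collect_coefficients(
            family, t.best_C, table, labels, plan,
            class_weight=class_weight, scale_per_fold=scale_per_fold,
        )
        tuning[family] = t
        samples[family] = s
        cis[family] = coefficient_cis(s, B=B, m=m, level=level, seed=seed)
    selection = select_features(cis["logistic"], cis["linear_svm"])
    return Stage1Result(selection=selection, tuning=tuning, samples=samples)
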