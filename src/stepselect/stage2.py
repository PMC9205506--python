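"""Stage 2: drop-column feature importance and the three-algorithm consensus.

For each of three mathematically distinct classifier families — logistic
regression, RBF-kernel support vector machine, and random forest — and each
train/test split of a shared Monte-Carlo plan, a benchmark model is fitted
on all candidate features and scored on the test fold; then, for every
feature, the model is refitted with that column removed (from both train and
test, since prediction requires matching columns) and rescored. The
importance of the feature on that split is

    importance = benchmark performance - dropped-column performance,

positive when the feature helps. Over the K splits this yields K importance
values per feature per algorithm; a percentile bootstrap CI for the *mean*
importance is computed, and a feature is important to an algorithm iff the
CI's lower bound is strictly positive. Features important to all three
algorithms are *primary* characteristics, to one or two *ancillary*, to none
*unimportant*.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .performance import MetricUndefinedError, get_metric
from .resampling import BootstrapCI, SplitPlan, bootstrap_ci, derive_seeds

__all__ = [
    "AlgorithmSpec",
    "DEFAULT_ALGORITHMS",
    "make_classifier",
    "ImportanceRecord",
    "drop_column_importance",
    "classify_importance",
    "ConsensusReport",
    "consensus",
]

CONSENSUS_FAMILIES = ("logistic", "rbf_svm", "random_forest")


@dataclass(frozen=True)
class AlgorithmSpec:
    """One classifier family with its (library-default) hyperparameters.

    Only ``class_weight`` is treated as tunable, mirroring the procedure's
    restraint about hyperparameter search in the importance stage.
    ``scale_per_fold=True`` wraps the estimator in a min-max scaler refitted
    on each training fold (leak-free mode); the default assumes the design
    matrix was scaled globally beforehand.
    """

    family: str
    class_weight: str | None = None
    params: dict = field(default_factory=dict)
    scale_per_fold: bool = False


DEFAULT_ALGORITHMS: tuple[AlgorithmSpec, ...] = tuple(
    AlgorithmSpec(f) for f in CONSENSUS_FAMILIES
)


def make_classifier(
    spec: AlgorithmSpec,
    split_seed: int | None = None,
    class_weight: str | None | object = "unset",
):
    """Build the sklearn estimator for ``spec``.

    ``split_seed`` seeds the stochastic families (the forest) so that within
    one split the benchmark fit and every dropped-column refit share the same
    randomness — importance differences then reflect the column, not seed
    noise. ``class_weight`` overrides the spec's value when given.
    """
    cw = spec.class_weight if class_weight == "unset" else class_weight
    if spec.family == "logistic":
        clf = LogisticRegression(class_weight=cw, **spec.params)
    elif spec.family == "rbf_svm":
        clf = SVC(kernel="rbf", class_weight=cw, **spec.params)
    elif spec.family == "random_forest":
        clf = RandomForestClassifier(
            random_state=split_seed, class_weight=cw, **spec.params
        )
    else:
        raise ValueError(f"unknown algorithm family {spec.family!r}")
    if spec.scale_per_fold:
        return Pipeline([("scale", MinMaxScaler(clip=False)), ("clf", clf)])
    return clf


@dataclass(frozen=True)
class ImportanceRecord:
    """Drop-column importances of one feature under one algorithm."""

    feature: str
    algorithm: str
    values: tuple[float, ...]  # one per usable split
    ci: BootstrapCI
    important: bool
    n_flagged_folds: int = 0


def classify_importance(ci: BootstrapCI) -> bool:
    """A feature is important iff its mean-importance CI is strictly positive."""
    return ci.lower > 0.0


def drop_column_importance(
    algorithm: AlgorithmSpec,
    table,
    labels,
    features: Sequence[str],
    plan: SplitPlan,
    metric="balanced_accuracy",
    seed: int = 0,
    B: int = 1000,
    m: int = 100,
    level: float = 0.95,
) -> list[ImportanceRecord]:
    """Drop-column importance of every feature in ``features`` under one algorithm.

    The same ``plan`` must be passed for all three algorithms of a consensus
    run. Folds on which the metric is undefined (a class absent from the test
    set) are flagged and excluded for all features of that split; the count is
    carried on every record.
    """
    features = list(features)
    missing = set(features) - set(table.features)
    if missing:
        raise ValueError(f"features not in table: {sorted(missing)}")
    metric_fn = get_metric(metric)
    y = np.asarray(labels)
    X_all = table.data[features].to_numpy()
    algo_tag = zlib.crc32(algorithm.family.encode()) % 100_000
    split_seeds = derive_seeds((seed + algo_tag) & 0x7FFFFFFF, plan.K)
    boot_seeds = derive_seeds((seed + algo_tag + 1) & 0x7FFFFFFF, len(features))

    per_feature: dict[str, list[float]] = {f: [] for f in features}
    flagged = 0
    for i, (train, test) in enumerate(plan):
        s = int(split_seeds[i])
        bench = make_classifier(algorithm, split_seed=s)
        bench.fit(X_all[train], y[train])
        try:
            bench_score = metric_fn(y[test], bench.predict(X_all[test]))
        except MetricUndefinedError:
            flagged += 1
            continue
        for j, feat in enumerate(features):
            cols = [k for k in range(len(features)) if k != j]
            clf = make_classifier(algorithm, split_seed=s)
            clf.fit(X_all[np.ix_(train, cols)], y[train])
            dropped_score = metric_fn(y[test], clf.predict(X_all[np.ix_(test, cols)]))
            per_feature[feat].append(bench_score - dropped_score)

    records = []
    for j, feat in enumerate(features):
        vals = per_feature[feat]
        if not vals:
            raise ValueError(
                f"metric undefined on every fold; no importances for {feat!r}"
            )
        ci = bootstrap_ci(vals, "mean", B=B, m=m, level=level, seed=int(boot_seeds[j]))
        records.append(
            ImportanceRecord(
                feature=feat,
                algorithm=algorithm.family,
                values=tuple(vals),
                ci=ci,
                important=classify_importance(ci),
                n_flagged_folds=flagged,
            )
        )
    return records


@dataclass(frozen=True)
class ConsensusReport:
    """Per-feature consensus class with the supporting importance records."""

    classes: dict[str, str]  # feature -> primary | ancillary | unimportant
    records: tuple[ImportanceRecord, ...]

    def features_in_class(self, cls: str) -> list[str]:
        return sorted(f for f, c in self.classes.items() if c == cls)

    @property
    def primary(self) -> list[str]:
        return self.features_in_class("primary")

    @property
    def ancillary(self) -> list[str]:
        return self.features_in_class("ancillary")

    @property
    def unimportant(self) -> list[str]:
        return self.features_in_class("unimportant")


def consensus(records: Iterable[ImportanceRecord]) -> ConsensusReport:
    """Classify features by how many of the three algorithms find them important.

    Important to all three families -> primary; to one or two -> ancillary;
    to none -> unimportant. All three families must be present and cover the
    same feature set.
    """
    records = tuple(records)
    by_algo: dict[str, dict[str, bool]] = {}
    for r in records:
        by_algo.setdefault(r.algorithm, {})[r.feature] = r.important
    missing = set(CONSENSUS_FAMILIES) - set(by_algo)
    if missing:
        raise ValueError(f"consensus undefined: missing algorithms {sorted(missing)}")
    feature_sets = {frozenset(d) for d in by_algo.values()}
    if len(feature_sets) != 1:
        raise ValueError("algorithms cover different feature sets")
    classes = {}
    for feat in sorted(next(iter(feature_sets))):
        votes = sum(by_algo[a][feat] for a in CONSENSUS_FAMILIES)
        classes[feat] = {3: "primary", 0: "unimportant"}.get(votes, "ancillary")
    return ConsensusReport(classes=classes, records=records)
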