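import numpy as np
import pytest

from stepselect.resampling import BootstrapCI, SplitPlan, generate_splits
from stepselect.stage2 import (
    AlgorithmSpec,
    ImportanceRecord,
    classify_importance,
    consensus,
    drop_column_importance,
)
from stepselect.synthetic import generate_cohort

from conftest import scaled_design, small_spec


def _ci(lower, upper):
    return BootstrapCI("mean", 0.95, 1000, 100, lower, upper, (lower + upper) / 2)


def _record(feature, algorithm, important):
    lo = 0.01 if important else -0.01
    return ImportanceRecord(feature, algorithm, (lo,), _ci(lo, lo + 0.05), important)


class TestClassifyImportance:
    @pytest.mark.parametrize(
        "lower,upper,expected",
        [(0.02, 0.09, True), (-0.01, 0.05, False), (0.0, 0.04, False)],
    )
    def test_strictly_positive_lower_bound(self, lower, upper, expected):
        assert classify_importance(_ci(lower, upper)) is expected


class TestConsensus:
    @pytest.mark.parametrize(
        "votes,expected",
        [
            (("logistic", "rbf_svm", "random_forest"), "primary"),
            (("logistic", "rbf_svm"), "ancillary"),
            (("random_forest",), "ancillary"),
            ((), "unimportant"),
        ],
    )
    def test_vote_count_classification(self, votes, expected):
        records = [
            _record("f", algo, algo in votes)
            for algo in ("logistic", "rbf_svm", "random_forest")
        ]
        report = consensus(records)
        assert report.classes["f"] == expected

    def test_missing_algorithm_is_an_error(self):
        records = [_record("f", "logistic", True), _record("f", "rbf_svm", True)]
        with pytest.raises(ValueError, match="missing algorithms"):
            consensus(records)

    def test_mismatched_feature_sets_rejected(self):
        records = [
            _record("f", "logistic", True),
            _record("g", "rbf_svm", True),
            _record("f", "random_forest", True),
        ]
        with pytest.raises(ValueError, match="different feature sets"):
            consensus(records)


class TestDropColumnImportance:
    def test_planted_signal_outranks_noise(self, small_cohort):
        # threshold at the latent mean: balanced classes, informative fits
        table, y = scaled_design(small_cohort, threshold=4300.0)
        plan = generate_splits(len(y), K=12, seed=3, labels=y)
        records = drop_column_importance(
            AlgorithmSpec("logistic"), table, y, table.features, plan,
            metric="balanced_accuracy", seed=1, m=12,
        )
        by_feat = {r.feature: r for r in records}
        assert by_feat["x0"].important
        assert by_feat["x0"].ci.estimate > by_feat["x2"].ci.estimate

    def test_duplicated_column_shares_and_loses_importance(self):
        cohort = generate_cohort(small_spec(seed=21, n=200, signal={"x0": 1800.0}))
        table, y = scaled_design(cohort, threshold=4300.0)
        plan = generate_splits(len(y), K=15, seed=8, labels=y)
        solo = drop_column_importance(
            AlgorithmSpec("logistic"), table, y, table.features, plan,
            metric="balanced_accuracy", seed=2, m=15,
        )
        solo_imp = {r.feature: r.ci.estimate for r in solo}["x0"]
        table.data["x0_copy"] = table.data["x0"]
        dup = drop_column_importance(
            AlgorithmSpec("logistic"), table, y, table.features, plan,
            metric="balanced_accuracy", seed=2, m=15,
        )
        dup_imp = {r.feature: r.ci.estimate for r in dup}
        # the surviving copy compensates, so each copy alone is worth less
        assert dup_imp["x0"] < solo_imp
        assert dup_imp["x0_copy"] < solo_imp

    def test_forest_importance_is_deterministic(self, small_cohort):
        table, y = scaled_design(small_cohort)
        plan = generate_splits(len(y), K=3, seed=5, labels=y)
        runs = [
            drop_column_importance(
                AlgorithmSpec("random_forest"), table, y, table.features, plan,
                metric="balanced_accuracy", seed=11, m=3,
            )
            for _ in range(2)
        ]
        for a, b in zip(*runs):
            assert a.values == b.values
            assert (a.ci.lower, a.ci.upper) == (b.ci.lower, b.ci.upper)

    def test_metric_undefined_folds_are_flagged_and_excluded(self):
        cohort = generate_cohort(small_spec(seed=9, n=40))
        table, _ = scaled_design(cohort)
        y = np.zeros(40, dtype=int)
        y[:3] = 1
        # hand-built plan: first test fold has no positives (balanced accuracy
        # undefined there), second fold has all three
        all_idx = np.arange(40)
        bad = (all_idx[:28], all_idx[28:])               # positives 0,1,2 in train
        good = (all_idx[2:30], np.r_[all_idx[:2], all_idx[30:]])  # positives both sides
        plan = SplitPlan(n=40, K=2, train_fraction=0.7, seed=None, splits=(bad, good))
        records = drop_column_importance(
            AlgorithmSpec("logistic"), table, y, table.features, plan,
            metric="balanced_accuracy", seed=0, m=2,
        )
        for r in records:
            assert r.n_flagged_folds == 1
            assert len(r.values) == 1

    def test_null_importance_is_unbiased_across_cohorts(self):
        """Dropping a pure-noise column carries no systematic gain or loss:
        pooled over 50 independent null cohorts and all features, the mean
        drop-column importance is indistinguishable from zero. (Within any
        one cohort a noise column can genuinely help or hurt, because its
        sampled correlation with the outcome is shared by the overlapping
        train and test folds; only the across-cohort average is zero.)"""
        estimates = []
        for rep in range(50):
            cohort = generate_cohort(small_spec(seed=700 + rep, n=120))
            table, y = scaled_design(cohort)
            plan = generate_splits(len(y), K=30, seed=rep, labels=y)
            records = drop_column_importance(
                AlgorithmSpec("logistic", class_weight="balanced"),
                table, y, table.features, plan,
                metric="balanced_accuracy", seed=rep, m=30,
            )
            estimates.extend(r.ci.estimate for r in records)
        assert abs(np.mean(estimates)) < 0.015

    def test_unknown_feature_rejected(self, small_cohort):
        table, y = scaled_design(small_cohort)
        plan = generate_splits(len(y), K=2, seed=0, labels=y)
        with pytest.raises(ValueError, match="not in table"):
            drop_column_importance(
                AlgorithmSpec("logistic"), table, y, ["ghost"], plan, seed=0
            )
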