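import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score

from stepselect.performance import (
    MetricUndefinedError,
    PerformanceSummary,
    balanced_accuracy,
    evaluate_models,
    precision_recall_curve,
    standard_accuracy,
    uninformed_baseline,
)
from stepselect.resampling import SplitPlan, generate_splits
from stepselect.stage2 import AlgorithmSpec, make_classifier

from conftest import scaled_design


class TestAccuracyMetrics:
    def test_constant_predictor_scores_half_balanced(self):
        y = [1] * 2 + [0] * 8
        assert balanced_accuracy(y, [0] * 10) == 0.5

    def test_hand_confusion_matrix(self):
        # 2 positives (1 found), 4 negatives (3 found): (0.5 + 0.75) / 2
        y_true = [1, 1, 0, 0, 0, 0]
        y_pred = [1, 0, 0, 0, 0, 1]
        assert balanced_accuracy(y_true, y_pred) == 0.625

    def test_perfect_predictions(self):
        y = [1, 0, 1, 0]
        assert balanced_accuracy(y, y) == 1.0
        assert standard_accuracy(y, y) == 1.0

    @pytest.mark.parametrize(
        "y_pred,expected", [([1, 0, 1, 1], 0.75), ([0, 1, 0, 1], 0.0)]
    )
    def test_standard_accuracy_fraction(self, y_pred, expected):
        assert standard_accuracy([1, 0, 1, 0], y_pred) == expected

    def test_single_class_truth_is_undefined_for_balanced(self):
        with pytest.raises(MetricUndefinedError):
            balanced_accuracy([1, 1, 1], [1, 0, 1])

    def test_agrees_with_sklearn_when_defined(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            balanced_accuracy_score(y_true, y_pred)
        )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(1, 20), st.integers(0, 10**6))
    def test_equal_class_sizes_make_the_metrics_agree(self, k, seed):
        rng = np.random.default_rng(seed)
        y_true = np.array([1] * k + [0] * k)
        y_pred = rng.integers(0, 2, 2 * k)
        assert balanced_accuracy(y_true, y_pred) == pytest.approx(
            standard_accuracy(y_true, y_pred)
        )


class TestUninformedBaseline:
    def test_printed_aerobic_threshold_value(self):
        assert round(100 * uninformed_baseline("standard_accuracy", 185 / 268), 2) == 57.24

    def test_balanced_baseline_ignores_imbalance(self):
        for p in (0.0, 0.1, 0.5, 0.9, 1.0):
            assert uninformed_baseline("balanced_accuracy", p) == 0.5

    def test_standard_baseline_minimized_at_even_split(self):
        grid = np.linspace(0, 1, 21)
        vals = [uninformed_baseline("standard_accuracy", p) for p in grid]
        assert all(v >= 0.5 for v in vals)
        assert [p for p, v in zip(grid, vals) if v == 0.5] == [0.5]


class TestPerformanceSummary:
    def test_stats_recomputable_from_scores(self):
        s = PerformanceSummary("logistic", "balanced_accuracy", "all_features",
                               scores=(0.6, 0.7, 0.8))
        assert s.mean == pytest.approx(0.7)
        assert s.min <= s.mean <= s.max
        assert s.sd == pytest.approx(np.std([0.6, 0.7, 0.8], ddof=1))


class TestEvaluateModels:
    def test_single_handbuilt_split_reduces_to_direct_score(self, small_cohort):
        table, y = scaled_design(small_cohort)
        n = len(y)
        train, test = np.arange(0, 84), np.arange(84, n)
        plan = SplitPlan(n=n, K=1, train_fraction=0.7, seed=None,
                         splits=((train, test),))
        out = evaluate_models(
            table, y, {"all_features": table.features},
            (AlgorithmSpec("logistic"),), plan, metric="balanced_accuracy", seed=0,
        )
        summary = out[("logistic", "all_features")]
        clf = make_classifier(AlgorithmSpec("logistic"))
        clf.fit(table.data.to_numpy()[train], y[train])
        direct = balanced_accuracy(y[test], clf.predict(table.data.to_numpy()[test]))
        assert summary.scores == (direct,)
        assert summary.mean == direct

    def test_class_weight_grid_reports_the_winner(self, small_cohort):
        table, y = scaled_design(small_cohort)
        plan = generate_splits(len(y), K=6, seed=1, labels=y)
        means = {}
        for cw in (None, "balanced"):
            out = evaluate_models(
                table, y, {"all_features": table.features},
                (AlgorithmSpec("logistic", class_weight=cw),), plan,
                metric="balanced_accuracy", seed=2,
            )
            means[cw] = out[("logistic", "all_features")].mean
        gridded = evaluate_models(
            table, y, {"all_features": table.features},
            (AlgorithmSpec("logistic"),), plan, metric="balanced_accuracy",
            class_weight_grid=(None, "balanced"), seed=2,
        )[("logistic", "all_features")]
        assert gridded.class_weight == max(means, key=means.get)
        assert gridded.mean == max(means.values())

    def test_empty_feature_set_rejected(self, small_cohort):
        table, y = scaled_design(small_cohort)
        plan = generate_splits(len(y), K=2, seed=0, labels=y)
        with pytest.raises(ValueError, match="empty"):
            evaluate_models(table, y, {"selected_features": []},
                            (AlgorithmSpec("logistic"),), plan, seed=0)


class TestPrecisionRecallCurve:
    def test_perfect_separation_has_unit_area(self):
        y = [0, 0, 0, 1, 1, 1]
        curve = precision_recall_curve([0.1, 0.2, 0.3, 0.7, 0.8, 0.9], y)
        assert curve.auc == 1.0
        assert curve.no_skill == 0.5

    def test_six_point_toy_matches_hand_enumeration(self):
        # predictor equals the labels except one negative scored positive
        y = np.array([1, 1, 1, 0, 0, 0])
        v = np.array([1.0, 1.0, 1.0, 1.0, 0.0, 0.0])
        curve = precision_recall_curve(v, y)
        # enumerate the two confusion tables by hand as the oracle
        # threshold <= 0: predict all positive: P=3/6, R=1
        # threshold in (0,1]: predict v>=1: TP=3, FP=1: P=3/4, R=1
        pairs = set(zip(np.round(curve.precision, 10), np.round(curve.recall, 10)))
        assert (0.75, 1.0) in pairs
        assert (1.0, 0.0) in pairs  # curve endpoint
        assert curve.auc == pytest.approx(0.75)

    def test_uninformative_predictor_tracks_prevalence(self):
        rng = np.random.default_rng(6)
        y = (rng.random(1000) < 0.3).astype(int)
        v = rng.normal(size=1000)
        curve = precision_recall_curve(v, y)
        prevalence = y.mean()
        assert abs(curve.auc - prevalence) < 0.05
        assert curve.no_skill == prevalence

    def test_recall_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        y = rng.integers(0, 2, 50)
        curve = precision_recall_curve(rng.normal(size=50), y)
        assert np.all(np.diff(curve.recall) <= 0)
        assert np.all((0 <= curve.precision) & (curve.precision <= 1))
        assert np.all((0 <= curve.recall) & (curve.recall <= 1))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_curve([0.2, 0.4], [1, 1])
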