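import math

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from dtirf.dataset import DatasetMatrix
from dtirf.evaluation import (
    METRIC_NAMES,
    ComparisonResult,
    ConfusionCounts,
    compare_models,
    confusion_counts,
    grid_search,
    kfold_cv,
    metrics,
    roc_auc,
)
from dtirf.rotation_forest import RotationForestConfig


def auc_bruteforce(y_true, scores):
    """Concordant-pair count (+ half ties) over all positive x negative pairs."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionCounts:
    def test_perfect_prediction(self):
        c = confusion_counts([1, 0, 1, 0], [1, 0, 1, 0])
        assert (c.tp, c.tn, c.fp, c.fn) == (2, 2, 0, 0)

    def test_all_positive_predictions(self):
        c = confusion_counts([1, 0], [1, 1])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 1, 0, 0)

    def test_matches_elementwise_tally(self):
        rng = np.random.default_rng(0)
        y_true = rng.integers(0, 2, size=100)
        y_pred = rng.integers(0, 2, size=100)
        c = confusion_counts(y_true, y_pred)
        tally = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
        for t, p in zip(y_true, y_pred):
            tally[("t" if t == p else "f") + ("p" if p == 1 else "n")] += 1
        assert (c.tp, c.fp, c.tn, c.fn) == (tally["tp"], tally["fp"], tally["tn"], tally["fn"])
        assert c.total == 100

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(tp=50, fp=0, tn=50, fn=0))
        assert m == {"accuracy": 1.0, "precision": 1.0, "sensitivity": 1.0, "mcc": 1.0}

    def test_known_counts(self):
        m = metrics(ConfusionCounts(tp=90, fp=10, tn=90, fn=10))
        assert m["accuracy"] == pytest.approx(0.9)
        assert m["precision"] == pytest.approx(0.9)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["mcc"] == pytest.approx(0.8)

    def test_matches_direct_formulas_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tp, fp, tn, fn = (int(v) for v in rng.integers(1, 100, size=4))
            m = metrics(ConfusionCounts(tp, fp, tn, fn))
            assert m["accuracy"] == pytest.approx((tp + tn) / (tp + fp + tn + fn), abs=1e-12)
            assert m["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)
            assert m["sensitivity"] == pytest.approx(tp / (tp + fn), abs=1e-12)
            expected_mcc = (tp * tn - fp * fn) / math.sqrt(
                (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
            )
            assert m["mcc"] == pytest.approx(expected_mcc, abs=1e-12)

    def test_undefined_metrics_are_none_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=10, fn=5))
        assert m["precision"] is None
        assert m["mcc"] is None
        assert m["sensitivity"] == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionCounts(0, 0, 0, 0))

    def test_independent_predictions_have_near_zero_mcc(self):
        rng = np.random.default_rng(2)
        y_true = rng.integers(0, 2, size=20000)
        y_pred = rng.integers(0, 2, size=20000)
        m = metrics(confusion_counts(y_true, y_pred))
        assert abs(m["mcc"]) < 0.02


class TestRocAuc:
    def test_perfect_ranking(self):
        auc, _ = roc_auc([1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0])
        assert auc == pytest.approx(1.0)

    def test_constant_scores_give_half(self):
        auc, _ = roc_auc([1, 0, 1, 0], [0.3, 0.3, 0.3, 0.3])
        assert auc == pytest.approx(0.5)

    @pytest.mark.parametrize("n", [6, 20, 50])
    def test_matches_pairwise_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(20):
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            auc, _ = roc_auc(y, scores)
            assert auc == pytest.approx(auc_bruteforce(y, scores), abs=1e-12)

    def test_roc_points_span_unit_square(self):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * 10)
        auc, points = roc_auc(y, rng.random(20))
        fprs, tprs = zip(*points)
        assert min(fprs) == 0 and max(fprs) == 1
        assert min(tprs) == 0 and max(tprs) == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])


def random_dataset(n=1270, d=12, seed=0, informative=False):
    rng = np.random.default_rng(seed)
    y = np.array([1] * (n // 2) + [0] * (n - n // 2))
    X = rng.normal(size=(n, d))
    if informative:
        X[:, 0] += 4 * y
    pairs = [(f"D{i}", f"T{i}") for i in range(n)]
    return DatasetMatrix(X=X, y=y, pairs=pairs)


def tree_factory(fold):
    return DecisionTreeClassifier(random_state=fold)


class TestKFoldCV:
    def test_folds_partition_indices(self):
        ds = random_dataset(n=1270)
        report = kfold_cv(ds, k=5, seed=0, classifier_factory=tree_factory)
        folds = report.fold_test_indices
        assert [len(f) for f in folds] == [254] * 5
        union = sorted(i for f in folds for i in f)
        assert union == list(range(1270))  # disjoint and exhaustive

    def test_mean_sd_recompute_from_folds(self):
        ds = random_dataset(n=200, informative=True, seed=1)
        report = kfold_cv(ds, k=5, seed=1, classifier_factory=tree_factory)
        for name in METRIC_NAMES:
            values = [f[name] for f in report.per_fold if f[name] is not None]
            assert report.mean[name] == pytest.approx(np.mean(values), abs=1e-12)
            assert report.sd[name] == pytest.approx(np.std(values, ddof=1), abs=1e-12)

    def test_separable_dataset_recovered(self, pipeline_dataset):
        cfg = RotationForestConfig(K=8, L=20, seed=0)
        report = kfold_cv(pipeline_dataset, cfg, k=5, seed=0)
        assert report.mean["accuracy"] >= 0.80
        assert report.mean["auc"] >= 0.90

    def test_insufficient_class_members_rejected(self):
        ds = random_dataset(n=8)
        with pytest.raises(ValueError, match="at least k"):
            kfold_cv(ds, k=5, seed=0, classifier_factory=tree_factory)

    def test_unstratified_flag(self):
        ds = random_dataset(n=100, informative=True)
        report = kfold_cv(ds, k=5, seed=0, stratified=False, classifier_factory=tree_factory)
        assert len(report.per_fold) == 5


class TestGridSearch:
    def test_single_cell_grid(self, pipeline_dataset):
        surface = grid_search(pipeline_dataset, [4], [3], k=3, seed=0)
        assert surface.best == (4, 3)
        assert surface.accuracy.shape == (1, 1)

    def test_consistency_with_independent_cv(self, pipeline_dataset):
        surface = grid_search(pipeline_dataset, [4], [2, 4], k=3, seed=5)
        for j, L in enumerate([2, 4]):
            cfg = RotationForestConfig(K=4, L=L, seed=5)
            report = kfold_cv(pipeline_dataset, cfg, k=3, seed=5)
            assert surface.accuracy[0, j] == pytest.approx(report.mean["accuracy"], abs=1e-15)

    def test_bit_reproducible(self, pipeline_dataset):
        a = grid_search(pipeline_dataset, [2, 4], [2], k=3, seed=7)
        b = grid_search(pipeline_dataset, [2, 4], [2], k=3, seed=7)
        assert np.array_equal(a.accuracy, b.accuracy)
        assert a.best == b.best

    def test_empty_grid_rejected(self, pipeline_dataset):
        with pytest.raises(ValueError):
            grid_search(pipeline_dataset, [], [2], k=3, seed=0)


class TestCompareModels:
    def test_identical_rows_no_difference(self):
        table = np.array([[0.9, 0.8, 0.7], [0.9, 0.8, 0.7]])
        result = compare_models(table)
        assert result.pvalue == 1.0
        assert result.statistic == 0.0

    def test_paired_t_matches_closed_form(self):
        ours = np.array([0.90, 0.88, 0.86, 0.80])
        other = np.array([0.85, 0.80, 0.84, 0.76])
        result = compare_models(np.vstack([ours, other]), method="paired_t")
        diffs = ours - other
        t = diffs.mean() / (diffs.std(ddof=1) / math.sqrt(len(diffs)))
        assert result.statistic == pytest.approx(t, abs=1e-12)
        assert 0 < result.pvalue < 1

    def test_swapping_models_negates_statistic(self):
        table = np.array([[0.9, 0.85, 0.8, 0.7], [0.8, 0.84, 0.7, 0.75]])
        a = compare_models(table)
        b = compare_models(table[::-1])
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_constant_nonzero_differences_rejected(self):
        table = np.array([[0.9, 0.8], [0.8, 0.7]])
        with pytest.raises(ValueError, match="constant"):
            compare_models(table)

    def test_wilcoxon_method(self):
        rng = np.random.default_rng(4)
        ours = 0.85 + 0.05 * rng.random(8)
        other = ours - 0.02 - 0.01 * rng.random(8)
        result = compare_models(np.vstack([ours, other]), method="wilcoxon")
        assert isinstance(result, ComparisonResult)
        assert result.pvalue < 0.05

    def test_pooling_of_multiple_competitors(self):
        ours = np.array([0.9, 0.8, 0.85])
        c1 = np.array([0.7, 0.75, 0.72])
        c2 = np.array([0.8, 0.65, 0.70])
        result = compare_models(np.vstack([ours, c1, c2]))
        direct = compare_models(np.vstack([ours, (c1 + c2) / 2]))
        assert result.statistic == pytest.approx(direct.statistic)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            compare_models(np.array([[0.9, 0.8]]))
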