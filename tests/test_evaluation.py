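"""Stratified folds, confusion-matrix metrics, chi-square rater comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pulmokit import evaluation
from pulmokit.ensemble_model import EnsembleSpec, TaskSpec, train_ensemble
from pulmokit.evaluation import (
    ConfusionCounts,
    compare_raters,
    compute_metrics,
    cross_validate,
    evaluate_prospective,
    stratified_folds,
)


class TestStratifiedFolds:
    def test_balanced_divisible_case(self):
        labels = ["a"] * 50 + ["b"] * 50
        assignment = stratified_folds(labels, K=10, seed=1)
        for fold in range(10):
            in_fold = np.asarray(labels, dtype=object)[assignment == fold]
            assert list(in_fold).count("a") == 5 and list(in_fold).count("b") == 5

    def test_uneven_case_within_one_of_share(self):
        labels = np.array(["a"] * 51 + ["b"] * 50, dtype=object)
        assignment = stratified_folds(labels, K=10, seed=2)
        sizes = np.bincount(assignment)
        assert set(sizes) <= {10, 11}
        for fold in range(10):
            fold_labels = labels[assignment == fold]
            for cls, total in (("a", 51), ("b", 50)):
                assert abs(list(fold_labels).count(cls) - total / 10) < 1.0

    def test_partition_property(self):
        labels = ["a"] * 23 + ["b"] * 31
        assignment = stratified_folds(labels, K=5, seed=0)
        assert assignment.size == 54 and set(assignment) == set(range(5))

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError, match="class"):
            stratified_folds(["a", "b", "b"], K=2)

    def test_seed_determinism(self):
        labels = ["a"] * 30 + ["b"] * 20
        a = stratified_folds(labels, K=5, seed=7)
        b = stratified_folds(labels, K=5, seed=7)
        np.testing.assert_array_equal(a, b)


class TestMetrics:
    def test_hand_computed_example(self):
        m = compute_metrics(ConfusionCounts(tp=3, tn=5, fp=1, fn=1), "positive_class")
        assert m.accuracy == pytest.approx(0.8)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.75)
        assert m.f1 == pytest.approx(0.75)

    def test_perfect_predictions(self):
        m = compute_metrics(ConfusionCounts(tp=4, tn=6, fp=0, fn=0), "macro")
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_zero_denominator_flagged(self):
        m = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=2, tn=8), "positive_class")
        assert m.precision == 0.0
        assert m.accuracy == pytest.approx(0.8)
        assert any("precision" in f for f in m.undefined_flags)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.tuples(*[st.integers(1, 50)] * 4), st.integers(2, 20))
    def test_scale_free(self, counts, factor):
        tp, fp, fn, tn = counts
        a = compute_metrics(ConfusionCounts(tp, fp, fn, tn), "macro")
        b = compute_metrics(
            ConfusionCounts(tp * factor, fp * factor, fn * factor, tn * factor), "macro"
        )
        assert a.accuracy == pytest.approx(b.accuracy)
        assert a.f1 == pytest.approx(b.f1)

    def test_f1_is_harmonic_mean(self):
        m = compute_metrics(ConfusionCounts(tp=7, fp=3, fn=2, tn=8), "positive_class")
        assert m.f1 == pytest.approx(2 * m.precision * m.recall / (m.precision + m.recall))

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))


class TestCrossValidate:
    def _blobs(self, n=60, distance=6.0):
        rng = np.random.default_rng(0)
        X = np.vstack([
            rng.standard_normal((n, 4)),
            rng.standard_normal((n, 4)) + distance,
        ])
        y = np.array(["normal"] * n + ["wheezing"] * n, dtype=object)
        return X, y

    def test_k_fold_reports_and_pooling(self):
        X, y = self._blobs()
        report, folds = cross_validate(
            X, y, TaskSpec.from_number(4), EnsembleSpec(n_members=2), K=5, seed=1
        )
        assert report.K == 5 and len(report.fold_metrics) == 5 and len(folds) == 5
        # pooled counts = sum over folds = one validation score per sample
        assert report.pooled_counts.total == 120

    def test_majority_stub_gives_majority_proportion(self, monkeypatch):
        # a classifier that always answers the majority class must pool
        # to exactly the majority-class proportion
        X = np.random.default_rng(1).standard_normal((100, 3))
        y = np.array(["normal"] * 70 + ["wheezing"] * 30, dtype=object)

        class StubEnsemble:
            pass

        monkeypatch.setattr(
            evaluation, "train_ensemble", lambda *a, **k: StubEnsemble()
        )
        monkeypatch.setattr(
            evaluation,
            "predict",
            lambda ens, Xv: np.array(["normal"] * len(Xv), dtype=object),
        )
        report, _ = cross_validate(X, y, TaskSpec.from_number(4), K=10, seed=0)
        assert report.pooled.accuracy == pytest.approx(0.70)

    def test_same_seed_reproduces_report(self):
        X, y = self._blobs(n=30)
        a, _ = cross_validate(X, y, TaskSpec.from_number(4), EnsembleSpec(n_members=1), K=3, seed=9)
        b, _ = cross_validate(X, y, TaskSpec.from_number(4), EnsembleSpec(n_members=1), K=3, seed=9)
        assert a.fold_assignment == b.fold_assignment
        assert a.pooled == b.pooled


class TestEvaluateProspective:
    def test_training_data_scores_perfectly_on_separable_blobs(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.standard_normal((30, 3)), rng.standard_normal((30, 3)) + 10])
        y = np.array(["normal"] * 30 + ["wheezing"] * 30, dtype=object)
        ens = train_ensemble(X, y, TaskSpec.from_number(4), EnsembleSpec(n_members=1))
        m = evaluate_prospective(ens, X, y)
        assert m.accuracy == 1.0

    def test_metrics_in_unit_interval(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.standard_normal((20, 3)), rng.standard_normal((20, 3)) + 1])
        y = np.array(["normal"] * 20 + ["wheezing"] * 20, dtype=object)
        ens = train_ensemble(X, y, TaskSpec.from_number(4), EnsembleSpec(n_members=2))
        m = evaluate_prospective(ens, rng.standard_normal((10, 3)) + 0.5,
                                 np.array(["normal"] * 5 + ["wheezing"] * 5, dtype=object))
        for v in (m.accuracy, m.precision, m.recall, m.f1):
            assert 0.0 <= v <= 1.0

    def test_empty_set_rejected(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.standard_normal((10, 3)), rng.standard_normal((10, 3)) + 5])
        y = np.array(["normal"] * 10 + ["wheezing"] * 10, dtype=object)
        ens = train_ensemble(X, y, TaskSpec.from_number(4), EnsembleSpec(n_members=1))
        with pytest.raises(ValueError):
            evaluate_prospective(ens, np.empty((0, 3)), np.array([], dtype=object))


def pearson_chi2_oracle(table):
    """Direct sum((O-E)^2 / E) on a 2x2 table."""
    table = np.asarray(table, dtype=float)
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    E = row @ col / table.sum()
    return float(((table - E) ** 2 / E).sum())


class TestCompareRaters:
    def test_identical_proportions_null(self):
        out = compare_raters(40, 50, 80, 100)
        assert out.chi_square_statistic == 0.0 and out.p_value == 1.0

    def test_matches_direct_formula_oracle(self):
        out = compare_raters(74, 90, 382, 450)
        expected = pearson_chi2_oracle([[74, 16], [382, 68]])
        assert out.chi_square_statistic == pytest.approx(expected)
        assert out.p_value == pytest.approx(stats.chi2.sf(expected, df=1))

    def test_yates_correction_never_larger(self):
        for mc, mt, rc, rt in [(74, 90, 382, 450), (10, 30, 25, 30), (5, 10, 9, 10)]:
            plain = compare_raters(mc, mt, rc, rt, continuity_correction=False)
            yates = compare_raters(mc, mt, rc, rt, continuity_correction=True)
            assert yates.chi_square_statistic <= plain.chi_square_statistic + 1e-12

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            compare_raters(0, 0, 10, 20)
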