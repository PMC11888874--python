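import numpy as np
import pytest

from helpers import brute_force_reduction

from cpetwave.classify import KernelSpec
from cpetwave.errors import ConfigError, DataError
from cpetwave.evaluate import (
    ConfusionMatrix,
    CVConfig,
    LabelMetrics,
    LabelReduction,
    binary_metrics,
    confusion,
    cross_validate,
    macro_average,
    make_folds,
    rank_models,
    reduce_label,
)
from cpetwave.features import FeatureConfig, Layout, build_feature_matrix
from cpetwave.records import Condition
from cpetwave.synthetic import SyntheticConfig, generate_cohort

HF, MS, H = Condition.HF, Condition.MS, Condition.H


class TestMakeFolds:
    def test_30_into_5(self):
        repeats = make_folds(30, CVConfig(k=5, repeats=1, seed=0))
        folds = repeats[0]
        assert len(folds) == 5
        assert all(f.size == 6 for f in folds)
        assert sorted(np.concatenate(folds)) == list(range(30))

    def test_45_into_5(self):
        folds = make_folds(45, CVConfig(k=5, repeats=1, seed=1))[0]
        assert [f.size for f in folds] == [9] * 5

    def test_uneven_sizes_differ_by_at_most_one(self):
        folds = make_folds(17, CVConfig(k=5, repeats=1, seed=2))[0]
        sizes = sorted(f.size for f in folds)
        assert sizes == [3, 3, 3, 4, 4]
        assert sorted(np.concatenate(folds)) == list(range(17))

    def test_seed_determinism_and_repeat_independence(self):
        a = make_folds(30, CVConfig(k=5, repeats=3, seed=7))
        b = make_folds(30, CVConfig(k=5, repeats=3, seed=7))
        for fa, fb in zip(a, b):
            for x, y in zip(fa, fb):
                np.testing.assert_array_equal(x, y)
        # different repeats give different partitions (overwhelmingly likely)
        assert any(
            not np.array_equal(x, y) for x, y in zip(a[0], a[1])
        )

    def test_n_smaller_than_k_rejected(self):
        with pytest.raises(ConfigError):
            make_folds(3, CVConfig(k=5, repeats=1, seed=0))


class TestConfusion:
    def test_perfect_diagonal(self):
        pred = [HF] * 15 + [MS] * 15 + [H] * 15
        cm = confusion(pred, pred, [HF, MS, H])
        np.testing.assert_array_equal(cm.counts, np.diag([15, 15, 15]))

    def test_rows_predicted_columns_true(self):
        cm = confusion([HF, MS], [MS, MS], [HF, MS])
        np.testing.assert_array_equal(cm.counts, [[0, 1], [0, 1]])

    def test_empty_inputs(self):
        cm = confusion([], [], [HF, MS])
        np.testing.assert_array_equal(cm.counts, np.zeros((2, 2)))

    def test_unknown_label_rejected(self):
        with pytest.raises(DataError, match="unknown label"):
            confusion([HF], [H], [HF, MS])


class TestReduceLabel:
    def test_perfect_classifier(self):
        cm = ConfusionMatrix([HF, MS, H], np.diag([15, 15, 15]))
        r = reduce_label(cm, 1)
        assert (r.TP, r.FP, r.FN, r.TN) == (15, 0, 0, 30)

    def test_worked_three_class_example(self):
        counts = np.array([[13, 2, 0], [1, 12, 1], [1, 1, 14]])
        cm = ConfusionMatrix([HF, MS, H], counts)
        r = reduce_label(cm, 2)
        assert (r.TP, r.FP, r.FN, r.TN) == (12, 2, 3, 28)
        assert (r.TP, r.FP, r.FN, r.TN) == brute_force_reduction(counts, 2)

    def test_conservation_identities(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(4, 4))
        cm = ConfusionMatrix([HF, MS, H, Condition.UNKNOWN], counts)
        total_tp = 0
        for m in range(1, 5):
            r = reduce_label(cm, m)
            assert r.total == counts.sum()
            total_tp += r.TP
        assert total_tp == np.trace(counts)

    def test_oracle_equivalence_random_matrices(self):
        # exact agreement with a brute-force one-vs-rest recount
        rng = np.random.default_rng(123)
        for _ in range(250):
            n = int(rng.integers(2, 6))
            counts = rng.integers(0, 12, size=(n, n))
            cm = ConfusionMatrix(list(range(n)), counts)
            for m in range(1, n + 1):
                r = reduce_label(cm, m)
                assert (r.TP, r.FP, r.FN, r.TN) == brute_force_reduction(counts, m)

    def test_two_class_matches_direct_formulas(self):
        counts = np.array([[11, 3], [4, 12]])  # rows predicted, cols true
        cm = ConfusionMatrix([HF, MS], counts)
        r = reduce_label(cm, 1)
        assert (r.TP, r.FP, r.FN, r.TN) == (11, 3, 4, 12)

    def test_index_out_of_range(self):
        cm = ConfusionMatrix([HF, MS], np.zeros((2, 2)))
        with pytest.raises(DataError):
            reduce_label(cm, 3)
        with pytest.raises(DataError):
            reduce_label(cm, 0)


class TestBinaryMetrics:
    def test_perfect(self):
        m = binary_metrics(LabelReduction(1, TP=15, FP=0, FN=0, TN=15))
        assert m.as_tuple() == (100.0, 100.0, 100.0, 100.0)

    def test_hand_computed_values(self):
        m = binary_metrics(LabelReduction(2, TP=12, FP=2, FN=3, TN=28))
        assert m.accuracy == pytest.approx(88.888, abs=1e-2)
        assert m.precision == pytest.approx(85.714, abs=1e-2)
        assert m.recall == pytest.approx(80.0, abs=1e-9)
        assert m.f1 == pytest.approx(82.758, abs=1e-2)

    def test_zero_over_zero_flagged(self):
        m = binary_metrics(LabelReduction(1, TP=0, FP=0, FN=5, TN=5))
        assert m.precision == 0.0
        assert m.recall == 0.0
        assert "precision" in m.undefined and "f1" in m.undefined

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            binary_metrics(LabelReduction(1, 0, 0, 0, 0))


class TestMacroAverage:
    def test_printed_worked_example(self):
        # (95 + 93 + 97) / 3 = 95, exactly
        macro = macro_average(
            [(95.0, 0, 0, 0), (93.0, 0, 0, 0), (97.0, 0, 0, 0)]
        )
        assert macro.accuracy == 95.0

    def test_single_label_identity(self):
        m = LabelMetrics(88.0, 77.0, 66.0, 71.0)
        assert macro_average([m]).as_tuple() == m.as_tuple()

    def test_zeros(self):
        assert macro_average([(0, 0, 0, 0)]).as_tuple() == (0, 0, 0, 0)


class TestMetricsSanity:
    def test_constant_classifier_macro_recall_is_chance(self):
        # constant HF predictions on balanced 3-class truth
        truth = [HF] * 15 + [MS] * 15 + [H] * 15
        cm = confusion([HF] * 45, truth, [HF, MS, H])
        per_label = [binary_metrics(reduce_label(cm, m)) for m in (1, 2, 3)]
        macro = macro_average(per_label)
        assert macro.recall == pytest.approx(100.0 / 3.0)

    def test_oracle_classifier_all_100(self):
        truth = [HF] * 5 + [MS] * 5 + [H] * 5
        cm = confusion(truth, truth, [HF, MS, H])
        per_label = [binary_metrics(reduce_label(cm, m)) for m in (1, 2, 3)]
        macro = macro_average(per_label)
        assert macro.as_tuple() == (100.0, 100.0, 100.0, 100.0)

    def test_micro_identity(self):
        rng = np.random.default_rng(9)
        counts = rng.integers(0, 10, size=(3, 3))
        cm = ConfusionMatrix([HF, MS, H], counts)
        micro = sum(reduce_label(cm, m).TP for m in (1, 2, 3)) / counts.sum()
        assert micro == pytest.approx(np.trace(counts) / counts.sum())


class TestCrossValidate:
    def test_separable_cohort_scores_100(self):
        cohort = generate_cohort(SyntheticConfig(n_per_class=15, delta=4.0, seed=1))
        fm = build_feature_matrix(cohort, FeatureConfig(layout=Layout.MW3))
        report = cross_validate(fm, KernelSpec(), CVConfig(k=5, repeats=5, seed=1))
        assert report.macro.accuracy == 100.0
        assert report.macro.recall == 100.0
        assert len(report.confusion_per_repeat) == 5

    def test_binary_path(self):
        cohort = generate_cohort(
            SyntheticConfig(n_per_class=10, classes=(HF, MS), delta=4.0, seed=2)
        )
        fm = build_feature_matrix(cohort, FeatureConfig(layout=Layout.BW3))
        report = cross_validate(fm, KernelSpec(), CVConfig(k=5, repeats=2, seed=2))
        assert report.per_label[HF].accuracy == 100.0
        assert report.classes == [HF, MS]

    def test_leave_one_out_on_tiny_separable_set(self):
        from cpetwave.features import FeatureMatrix

        values = np.array([[0.0], [0.1], [0.2], [5.0], [5.1], [5.2]])
        fm = FeatureMatrix(
            layout=Layout.X,
            values=values,
            feature_names=["f__raw__mean"],
            labels=[HF, HF, HF, MS, MS, MS],
            row_ids=[f"s{i}" for i in range(6)],
        )
        report = cross_validate(fm, KernelSpec(), CVConfig(k=6, repeats=1, seed=0))
        assert report.macro.accuracy == 100.0

    def test_report_serializes(self):
        cohort = generate_cohort(SyntheticConfig(n_per_class=5, delta=4.0, seed=3))
        fm = build_feature_matrix(cohort, FeatureConfig(layout=Layout.MW3))
        report = cross_validate(fm, KernelSpec(), CVConfig(k=5, repeats=1, seed=3))
        payload = report.to_dict()
        assert payload["k"] == 5 and payload["repeats"] == 1 and payload["seed"] == 3
        assert set(payload["per_label"]) == {"HF", "MS", "H"}

    def test_skipped_fold_warning_when_class_missing(self):
        # one HF subject: leave-one-out makes one training split lack HF
        cohort = generate_cohort(SyntheticConfig(n_per_class=3, delta=4.0, seed=4))
        fm = build_feature_matrix(cohort[:7], FeatureConfig(layout=Layout.MW3))
        # cohort[:7] = 3 HF + 3 MS + 1 H
        report = cross_validate(fm, KernelSpec(), CVConfig(k=7, repeats=1, seed=4))
        assert len(report.warnings) == 1
        assert report.confusion_per_repeat[0].total == 6


class TestRankModels:
    def _report(self, accuracy, f1=50.0):
        macro = LabelMetrics(accuracy, 50.0, 50.0, f1)
        from cpetwave.evaluate import MetricsReport

        return MetricsReport(
            classes=[HF, MS, H],
            per_label={},
            macro=macro,
            confusion_per_repeat=[],
            k=5,
            repeats=5,
            seed=0,
        )

    def test_descending_accuracy(self):
        table = rank_models(
            {"B": self._report(92.0), "A": self._report(95.0), "C": self._report(86.0)}
        )
        assert list(table["method"]) == ["A", "B", "C"]
        assert list(table["rank"]) == [1, 2, 3]

    def test_tie_broken_by_f1_then_name(self):
        table = rank_models(
            {
                "Z": self._report(90.0, f1=40.0),
                "A": self._report(90.0, f1=60.0),
                "B": self._report(90.0, f1=60.0),
            }
        )
        assert list(table["method"]) == ["A", "B", "Z"]

    def test_single_report(self):
        table = rank_models({"only": self._report(70.0)})
        assert list(table["rank"]) == [1]
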