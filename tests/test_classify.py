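"""SVM cross-validation harness and the 1-s.d. size rule."""

import numpy as np
import pandas as pd
import pytest

import pollenmorph as pm
from pollenmorph.classify import INDETERMINATE
from pollenmorph.ordination import SummaryStats


def stats(mean, sd, n=100):
    return SummaryStats(n=n, mean=mean, sd=sd,
                        range_1sd=(mean - sd, mean + sd),
                        range_2sd=(mean - 2 * sd, mean + 2 * sd),
                        min=mean - 3 * sd, max=mean + 3 * sd)


class TestSvmCv:
    def test_separable_classes_are_perfect(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.uniform(0, 1, 200), rng.uniform(5, 6, 200)])
        y = ["a"] * 200 + ["b"] * 200
        df = pd.DataFrame({"f": x})
        report = pm.svm_cv(df, y, pm.CVConfig(n_iter=10, seed=1))
        assert report.mean_accuracy == pytest.approx(100.0)

    def test_permuted_labels_are_chance(self):
        """Random labels on balanced classes give ~50% accuracy."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(500, 5)))
        y = rng.permutation(["a"] * 250 + ["b"] * 250)
        report = pm.svm_cv(df, y, pm.CVConfig(n_iter=20, seed=2))
        assert abs(report.mean_accuracy - 50.0) < 3.0

    def test_single_class_rejected(self):
        df = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0, 5.0]})
        with pytest.raises(ValueError):
            pm.svm_cv(df, ["a"] * 5, pm.CVConfig(n_iter=2))

    def test_report_consistency(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(200, 3)))
        df.iloc[:100] += 1.5
        y = ["a"] * 100 + ["b"] * 100
        report = pm.svm_cv(df, y, pm.CVConfig(n_iter=15, seed=4))
        assert report.mean_accuracy == pytest.approx(
            float(np.mean(report.accuracies)), abs=1e-9)
        assert report.sd_accuracy == pytest.approx(
            float(np.std(report.accuracies, ddof=1)), abs=1e-9)
        assert np.all((report.accuracies >= 0) & (report.accuracies <= 100))
        assert set(report.per_class_recall) == {"a", "b"}
        assert report.majority_baseline == pytest.approx(50.0)

    def test_stratified_mode(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(120, 2)))
        df.iloc[:90] += 2.0
        y = ["a"] * 90 + ["b"] * 30
        report = pm.svm_cv(df, y,
                           pm.CVConfig(n_iter=5, seed=6, stratified=True))
        assert report.mean_accuracy > 80.0
        assert report.majority_baseline == pytest.approx(75.0)

    def test_imbalanced_baseline_on_cohort(self, cv_all50_polar):
        """The report carries the majority-class baseline (~75% for the 3:1
        study imbalance) and per-genus recall."""
        report = cv_all50_polar
        assert report.majority_baseline == pytest.approx(75.0, abs=2.0)
        assert set(report.per_class_recall) == {"leptospermum", "kunzea"}
        assert min(report.per_class_recall.values()) > 80.0


class TestAccuracyOrdering:
    def test_table_pattern_on_calibrated_cohort(self, cv_grid_both):
        """More features help (all50 >= core7 per view set) and polar-view
        grains are easier (polar_only >= both per feature set)."""
        acc = {k: v.mean_accuracy for k, v in cv_grid_both.items()}
        assert acc[("all50", "polar_only")] > acc[("core7", "polar_only")]
        assert acc[("all50", "both")] > acc[("core7", "both")]
        assert acc[("all50", "polar_only")] > acc[("all50", "both")]
        assert acc[("core7", "polar_only")] > acc[("core7", "both")]


class TestSizeRule:
    # the study's published 1-s.d. E ranges, μm
    LEPTO = stats(20.19, 1.31)   # spans 18.88 - 21.50
    KUNZEA = stats(16.66, 1.17)  # spans 15.49 - 17.83

    def test_printed_range_examples(self):
        labels = pm.size_rule_classify([20.0, 17.0, 18.3],
                                       self.LEPTO, self.KUNZEA,
                                       label_a="leptospermum",
                                       label_b="kunzea")
        assert labels == ["leptospermum", "kunzea", INDETERMINATE]

    def test_overlapping_ranges_give_indeterminate(self):
        a, b = stats(10.0, 2.0), stats(11.0, 2.0)
        labels = pm.size_rule_classify([10.5], a, b)
        assert labels == [INDETERMINATE]

    def test_identical_ranges_all_indeterminate(self):
        a = stats(10.0, 1.0)
        labels = pm.size_rule_classify([9.5, 10.0, 10.5], a, a)
        assert labels == [INDETERMINATE] * 3

    def test_empty_input(self):
        assert pm.size_rule_classify([], self.LEPTO, self.KUNZEA) == []

    def test_boundary_inclusive(self):
        a, b = stats(10.0, 1.0), stats(20.0, 1.0)
        assert pm.size_rule_classify([9.0, 11.0], a, b) == ["a", "a"]
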