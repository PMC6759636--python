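"""Evaluation protocols and metrics: splits, PPV, confusion matrices, ROC,
and the timing harness."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import motionprims as mp
from motionprims.evaluation import ConfusionMatrix


def _toy_table(n_segments_per_class=10, windows_per_segment=4, n_subjects=2,
               p=3, separation=3.0, seed=0):
    """Small labeled feature table with segment/subject structure."""
    rng = np.random.default_rng(seed)
    rows = []
    seg_id = 0
    for ci, c in enumerate(mp.CLASSES):
        for _ in range(n_segments_per_class):
            subject = f"s{seg_id % n_subjects:02d}"
            center = separation * ci
            for w in range(windows_per_segment):
                rows.append(
                    {
                        "subject_id": subject,
                        "segment_id": seg_id,
                        "window_label": c,
                        "window_start_s": 0.1 * w,
                        **{
                            f"f{j}": center + rng.normal()
                            for j in range(p)
                        },
                    }
                )
            seg_id += 1
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_exact_fraction_of_segments_per_class(self):
        table = _toy_table(n_segments_per_class=10)
        plan = mp.SplitPlan(train_fraction=0.6, n_repeats=1, seed=1)
        train, test = mp.stratified_split(table, plan, 0)
        for c in mp.CLASSES:
            n_train = train.loc[train.window_label == c, "segment_id"].nunique()
            n_test = test.loc[test.window_label == c, "segment_id"].nunique()
            assert (n_train, n_test) == (6, 4)

    def test_disjoint_and_exhaustive_at_segment_level(self):
        table = _toy_table()
        plan = mp.SplitPlan(seed=2)
        train, test = mp.stratified_split(table, plan, 3)
        assert set(train.segment_id) & set(test.segment_id) == set()
        assert len(train) + len(test) == len(table)

    def test_test_proportions_within_one_segment_of_full_table(self):
        table = _toy_table(n_segments_per_class=13)
        plan = mp.SplitPlan(train_fraction=0.6, seed=3)
        _, test = mp.stratified_split(table, plan, 0)
        per_class = test.groupby("window_label")["segment_id"].nunique()
        assert per_class.max() - per_class.min() <= 1

    def test_single_segment_class_error_names_class(self):
        table = _toy_table(n_segments_per_class=1)
        with pytest.raises(mp.InvalidArgumentError, match="reach"):
            mp.stratified_split(table, mp.SplitPlan(seed=1), 0)

    def test_seeded_per_repeat(self):
        table = _toy_table()
        plan = mp.SplitPlan(seed=5)
        a1, _ = mp.stratified_split(table, plan, 0)
        a2, _ = mp.stratified_split(table, plan, 0)
        b, _ = mp.stratified_split(table, plan, 1)
        pd.testing.assert_frame_equal(a1, a2)
        assert set(a1.segment_id) != set(b.segment_id)

    def test_plan_requires_seed(self):
        with pytest.raises(mp.InvalidArgumentError):
            mp.SplitPlan(scheme="stratified_repeats", seed=None)


class TestLosoSplits:
    def test_one_fold_per_subject_partitioning_the_table(self):
        table = _toy_table(n_subjects=6)
        folds = mp.loso_splits(table)
        assert len(folds) == 6
        seen = []
        for train, test in folds:
            assert test["subject_id"].nunique() == 1
            assert set(train.subject_id) & set(test.subject_id) == set()
            seen.append(test)
        combined = pd.concat(seen).sort_index()
        pd.testing.assert_frame_equal(combined, table)

    def test_single_subject_rejected(self):
        table = _toy_table(n_subjects=1)
        with pytest.raises(mp.InvalidArgumentError):
            mp.loso_splits(table)


class TestPpvScores:
    def test_perfect_diagonal_gives_100_everywhere(self):
        cm = ConfusionMatrix(mp.CLASSES, np.diag([5, 6, 7, 8]))
        per_class, overall = mp.ppv_scores(cm)
        assert all(v == 100.0 for v in per_class.values())
        assert overall == 100.0

    def test_hand_counted_example(self):
        # y_true=(r,r,t,t), y_pred=(r,t,t,t)
        cm = ConfusionMatrix.from_labels(
            ["reach", "reach", "transport", "transport"],
            ["reach", "transport", "transport", "transport"],
        )
        per_class, overall = mp.ppv_scores(cm)
        assert per_class["reach"] == pytest.approx(100.0)
        assert per_class["transport"] == pytest.approx(200.0 / 3, abs=1e-9)
        assert overall == pytest.approx(75.0)

    def test_micro_pooled_ppv_equals_accuracy_on_random_matrices(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 30, size=(4, 4))
            if counts.sum() == 0:
                continue
            cm = ConfusionMatrix(mp.CLASSES, counts)
            _, overall = mp.ppv_scores(cm)
            assert overall == pytest.approx(
                100.0 * np.trace(counts) / counts.sum(), abs=1e-9
            )

    def test_never_predicted_class_is_nan(self):
        counts = np.array([[3, 0, 0, 0], [3, 0, 0, 0], [0, 0, 2, 0], [0, 0, 0, 2]])
        per_class, _ = mp.ppv_scores(ConfusionMatrix(mp.CLASSES, counts))
        assert np.isnan(per_class["transport"])

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(mp.InvalidArgumentError):
            mp.ppv_scores(ConfusionMatrix(mp.CLASSES, np.zeros((4, 4), dtype=int)))

    def test_row_percent_rows_sum_to_100(self, rng):
        counts = rng.integers(1, 20, size=(4, 4))
        cm = ConfusionMatrix(mp.CLASSES, counts)
        assert np.allclose(cm.row_percent.sum(axis=1), 100.0, atol=1e-6)


class TestRocAnalysis:
    def _binary_scores(self, values):
        v = np.asarray(values, dtype=float)
        return mp.ScoreMatrix(np.column_stack([1 - v, v]), ("neg", "pos"))

    def test_perfectly_separating_scores_auc_one_operating_corner(self):
        scores = self._binary_scores([0.9, 0.8, 0.4, 0.2])
        roc = mp.roc_analysis(scores, ["pos", "pos", "neg", "neg"])
        assert roc["pos"].auc == pytest.approx(1.0)
        assert roc["pos"].operating_point["fpr"] == 0.0
        assert roc["pos"].operating_point["tpr"] == 1.0

    def test_half_concordant_scores_auc_half(self):
        scores = self._binary_scores([0.9, 0.8, 0.4, 0.2])
        roc = mp.roc_analysis(scores, ["pos", "neg", "neg", "pos"])
        assert roc["pos"].auc == pytest.approx(0.5)

    def test_auc_equals_concordance_fraction_oracle(self, rng):
        """AUC must equal P(score+ > score-) + P(tie)/2 by pair enumeration."""
        for _ in range(100):
            n = int(rng.integers(6, 30))
            s = np.round(rng.uniform(size=n), 2)  # rounding induces ties
            y = rng.choice(["pos", "neg"], size=n)
            if len(set(y)) < 2:
                continue
            roc = mp.roc_analysis(self._binary_scores(s), y)
            pos, neg = s[y == "pos"], s[y == "neg"]
            wins = (pos[:, None] > neg[None, :]).sum()
            ties = (pos[:, None] == neg[None, :]).sum()
            expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
            assert roc["pos"].auc == pytest.approx(expected, abs=1e-12)

    @given(scale=st.floats(0.1, 5.0), shift=st.floats(-2.0, 2.0))
    def test_auc_invariant_to_monotone_transforms(self, scale, shift):
        rng = np.random.default_rng(99)
        s = rng.uniform(size=40)
        y = rng.choice(["pos", "neg"], size=40)
        base = mp.roc_analysis(self._binary_scores(s), y)["pos"].auc
        warped = mp.roc_analysis(
            self._binary_scores(np.exp(scale * s) + shift), y
        )["pos"].auc
        assert warped == pytest.approx(base, abs=1e-12)

    def test_curve_anchored_and_monotone(self, rng):
        s = rng.uniform(size=50)
        y = rng.choice(["pos", "neg"], size=50)
        r = mp.roc_analysis(self._binary_scores(s), y)["pos"]
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(r.fpr) >= 0).all() and (np.diff(r.tpr) >= 0).all()

    def test_absent_class_skipped_with_warning(self):
        scores = mp.ScoreMatrix(np.random.rand(4, 2), ("a", "b"))
        with pytest.warns(UserWarning):
            roc = mp.roc_analysis(scores, ["a", "a", "a", "a"])
        assert roc == {}

    def test_closest_corner_method_supported(self, rng):
        s = rng.uniform(size=30)
        y = rng.choice(["pos", "neg"], size=30)
        r = mp.roc_analysis(self._binary_scores(s), y, method="closest")["pos"]
        assert 0 <= r.operating_point["fpr"] <= 1


class TestEvaluate:
    def test_separable_table_gives_100_overall_ppv(self):
        table = _toy_table(separation=20.0)
        plan = mp.SplitPlan(n_repeats=3, seed=4)
        report = mp.evaluate(table, ["lda", "nbc", "knn", "svm"], plan)
        for name, r in report.results.items():
            assert r.overall_ppv_mean == pytest.approx(100.0), name

    def test_permuted_labels_give_chance_level_ppv(self, rng):
        table = _toy_table(n_segments_per_class=15, separation=2.0, seed=3)
        # destroy the feature-label association segment-wise
        perm = table.copy()
        seg_labels = perm.groupby("segment_id")["window_label"].first()
        shuffled = pd.Series(
            rng.permutation(seg_labels.values), index=seg_labels.index
        )
        perm["window_label"] = perm["segment_id"].map(shuffled)
        report = mp.evaluate(
            perm, ["lda"], mp.SplitPlan(n_repeats=10, seed=4), compute_roc=False
        )
        majority = 25.0  # four equally frequent classes
        n_test = report.results["lda"].confusion.counts.sum() / 10
        se = 100.0 * np.sqrt(0.25 * 0.75 / n_test)
        assert abs(report.results["lda"].overall_ppv_mean - majority) <= 3 * se

    def test_report_identical_across_runs_with_same_seed(self):
        table = _toy_table()
        plan = mp.SplitPlan(n_repeats=2, seed=7)
        a = mp.evaluate(table, ["lda"], plan)
        b = mp.evaluate(table, ["lda"], plan)
        assert a.to_dict() == b.to_dict()

    def test_loso_scheme_averages_over_subject_folds(self):
        table = _toy_table(n_subjects=3, separation=20.0)
        report = mp.evaluate(table, ["lda"], mp.SplitPlan(scheme="loso"))
        assert len(report.results["lda"].overall_ppv_per_repeat) == 3

    def test_report_table_layout(self):
        table = _toy_table(separation=20.0)
        report = mp.evaluate(table, ["lda", "nbc"], mp.SplitPlan(n_repeats=2, seed=1))
        frame = report.to_frame()
        assert list(frame["algorithm"]) == ["lda", "nbc"]
        assert "overall_ppv_mean" in frame.columns
        assert "reach_ppv_mean" in frame.columns

    def test_roc_computed_per_class(self):
        table = _toy_table(separation=20.0)
        report = mp.evaluate(table, ["lda"], mp.SplitPlan(n_repeats=2, seed=1))
        roc = report.results["lda"].roc
        assert set(roc) == set(mp.CLASSES)
        for r in roc.values():
            assert r.auc == pytest.approx(1.0)


class TestTimingBenchmark:
    def test_one_row_per_algorithm_fraction_pair(self):
        table = _toy_table(n_segments_per_class=20)
        report = mp.timing_benchmark(
            table, ["lda", "knn"], mp.LARGE_DATASET_FRACTIONS, seed=0
        )
        frame = report.to_frame()
        assert len(frame) == 2 * len(mp.LARGE_DATASET_FRACTIONS)
        assert set(frame["algorithm"]) == {"lda", "knn"}

    def test_default_fraction_grids(self):
        assert mp.SMALL_DATASET_FRACTIONS == (
            0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0,
        )
        assert mp.LARGE_DATASET_FRACTIONS == (0.25, 0.5, 0.75, 1.0)

    def test_invalid_fractions_rejected(self):
        table = _toy_table()
        for bad in ([], [0.5, 0.5], [0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(mp.InvalidArgumentError):
                mp.timing_benchmark(table, ["lda"], bad, seed=0)
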