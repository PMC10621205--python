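"""Class balancing, train/test evaluation, selection and annotation."""

from __future__ import annotations

from datetime import datetime, timezone

import numpy as np
import pandas as pd
import pytest

from kratkit import classify, features, synth
from kratkit.classify import Algorithm, ModelReport, ModelSpec
from kratkit.core import AccelTrace, BEHAVIOR_NAMES


def _fake_table(counts: dict[str, int], seed=0) -> pd.DataFrame:
    """Minimal labeled feature table with separable per-class features."""
    rng = np.random.default_rng(seed)
    rows = []
    # each class gets its own feature direction so the classes are
    # linearly separable one-vs-rest
    k = len(features.FEATURE_NAMES)
    centers = {}
    for i, b in enumerate(BEHAVIOR_NAMES):
        mu = np.zeros(k)
        mu[i * (k // 4) : (i + 1) * (k // 4)] = 10.0
        centers[b] = mu
    for b, n in counts.items():
        for _ in range(n):
            vals = rng.normal(centers[b], 0.5)
            row = dict(zip(features.FEATURE_NAMES, vals))
            row["label"] = b
            rows.append(row)
    return pd.DataFrame(rows)


class TestBalance:
    def test_subsamples_to_rarest_class(self):
        table = _fake_table(
            {"motionless": 100, "travel": 80, "foraging": 30, "grooming": 45}
        )
        out = classify.balance_classes(table, seed=0)
        assert len(out) == 120
        assert out["label"].value_counts().eq(30).all()

    def test_already_balanced_input_membership_unchanged(self):
        table = _fake_table({b: 20 for b in BEHAVIOR_NAMES})
        out = classify.balance_classes(table, seed=1)
        assert sorted(out.index) == sorted(table.index)

    def test_deterministic_under_seed(self):
        table = _fake_table({"motionless": 50, "travel": 40, "foraging": 20, "grooming": 30})
        a = classify.balance_classes(table, seed=7)
        b = classify.balance_classes(table, seed=7)
        assert list(a.index) == list(b.index)

    def test_absent_class_is_an_error_listing_counts(self):
        table = _fake_table({"motionless": 10, "travel": 10, "foraging": 10, "grooming": 0})
        with pytest.raises(ValueError, match="grooming"):
            classify.balance_classes(table, seed=0)


class TestSplit:
    def test_stratified_half_split(self):
        table = _fake_table({b: 30 for b in BEHAVIOR_NAMES})
        train, test = classify.split_train_test(table, 0.5, seed=0)
        assert len(train) == len(test) == 60
        assert train["label"].value_counts().eq(15).all()
        assert test["label"].value_counts().eq(15).all()
        assert set(train.index).isdisjoint(test.index)
        assert sorted([*train.index, *test.index]) == sorted(table.index)

    def test_degenerate_fractions_rejected(self):
        table = _fake_table({b: 10 for b in BEHAVIOR_NAMES})
        for frac in (0.0, 1.0):
            with pytest.raises(ValueError):
                classify.split_train_test(table, frac, seed=0)

    def test_deterministic_partition(self):
        table = _fake_table({b: 25 for b in BEHAVIOR_NAMES})
        a1, _ = classify.split_train_test(table, 0.5, seed=3)
        a2, _ = classify.split_train_test(table, 0.5, seed=3)
        assert list(a1.index) == list(a2.index)


class TestMetrics:
    def test_precision_recall_from_defining_formulas(self):
        # one class with TP=9, FP=1, FN=3: precision 0.90, recall 0.75
        cm = np.array(
            [
                [9, 1, 1, 1],  # travel-row contributes 1 FP to motionless
                [1, 20, 0, 0],
                [1, 0, 20, 0],
                [1, 0, 0, 20],
            ]
        )
        # motionless: TP=9, FP=3 -> adjust to the stated case
        cm = np.array(
            [
                [9, 3, 0, 0],
                [1, 20, 0, 0],
                [0, 0, 20, 0],
                [0, 0, 0, 20],
            ]
        )
        spec = ModelSpec(Algorithm.DECISION_TREE, "all", 6.0)
        rep = ModelReport(spec=spec, confusion=cm, train_sizes={}, test_sizes={})
        assert rep.per_class_precision["motionless"] == pytest.approx(0.90)
        assert rep.per_class_recall["motionless"] == pytest.approx(0.75)

    def test_bookkeeping_recomputed_from_matrix(self):
        rng = np.random.default_rng(0)
        cm = rng.integers(0, 40, size=(4, 4))
        spec = ModelSpec(Algorithm.RANDOM_FOREST, "all", 2.0)
        rep = ModelReport(spec=spec, confusion=cm, train_sizes={}, test_sizes={})
        total = cm.sum()
        for i, b in enumerate(BEHAVIOR_NAMES):
            tp = cm[i, i]
            fp = cm[:, i].sum() - tp
            fn = cm[i, :].sum() - tp
            tn = total - tp - fp - fn
            assert rep.per_class_precision[b] == pytest.approx(
                tp / (tp + fp), abs=1e-12
            )
            assert rep.per_class_recall[b] == pytest.approx(tp / (tp + fn), abs=1e-12)
            assert rep.per_class_accuracy[b] == pytest.approx(
                (tp + tn) / total, abs=1e-12
            )
        assert rep.overall_accuracy == pytest.approx(np.trace(cm) / total, abs=1e-12)

    def test_confusion_counts_sum_to_test_size(self, training_tables):
        table = training_tables[6.0]
        balanced = classify.balance_classes(table, seed=0)
        train, test = classify.split_train_test(balanced, 0.5, seed=1)
        rep = classify.evaluate_model(
            ModelSpec(Algorithm.DECISION_TREE, "reduced", 6.0), train, test
        )
        assert rep.confusion.sum() == len(test)


class TestEvaluate:
    def test_separable_classes_classify_perfectly(self):
        table = _fake_table({b: 40 for b in BEHAVIOR_NAMES})
        train, test = classify.split_train_test(table, 0.5, seed=0)
        for algo in Algorithm:
            rep = classify.evaluate_model(ModelSpec(algo, "all", 6.0), train, test)
            assert rep.overall_accuracy == 1.0
            assert np.all(rep.confusion == np.diag(np.diag(rep.confusion)))

    def test_permuted_labels_score_at_chance(self):
        rng = np.random.default_rng(12)
        table = _fake_table({b: 120 for b in BEHAVIOR_NAMES})
        table["label"] = rng.permutation(table["label"].to_numpy())
        balanced = classify.balance_classes(table, seed=0)
        train, test = classify.split_train_test(balanced, 0.5, seed=0)
        rep = classify.evaluate_model(
            ModelSpec(Algorithm.DECISION_TREE, "all", 6.0, seed=0), train, test
        )
        n = len(test)
        se = np.sqrt(0.25 * 0.75 / n)
        assert abs(rep.overall_accuracy - 0.25) <= 3 * se

    def test_non_finite_features_error_names_column(self):
        table = _fake_table({b: 10 for b in BEHAVIOR_NAMES})
        train, test = classify.split_train_test(table, 0.5, seed=0)
        train = train.copy()
        train.loc[train.index[0], "odba"] = np.nan
        with pytest.raises(ValueError, match="odba"):
            classify.evaluate_model(ModelSpec(Algorithm.LINEAR_SVM, "all", 6.0), train, test)


class TestSelection:
    def test_single_spec_grid_returns_it(self, training_tables):
        res = classify.model_selection(
            {6.0: training_tables[6.0]},
            algorithms=[Algorithm.DECISION_TREE],
            feature_sets=("reduced",),
            seed=0,
        )
        assert res.best.spec.algorithm == Algorithm.DECISION_TREE
        assert len(res.leaderboard) == 1

    def test_leaderboard_monotone_in_selection_score(self, training_tables):
        res = classify.model_selection(training_tables, seed=0)
        scores = res.leaderboard["selection_score"].to_numpy()
        assert np.all(np.diff(scores) <= 1e-12)
        # score recomputable from persisted metrics
        re = (
            res.leaderboard[["macro_accuracy", "macro_precision", "macro_recall"]]
            .mean(axis=1)
            .to_numpy()
        )
        assert np.allclose(re, scores)

    def test_selection_is_deterministic(self, training_tables):
        r1 = classify.model_selection(training_tables, seed=0)
        r2 = classify.model_selection(training_tables, seed=0)
        assert r1.best.spec == r2.best.spec
        pd.testing.assert_frame_equal(r1.leaderboard, r2.leaderboard)


class TestAnnotate:
    def _trained_report(self, training_tables):
        table = training_tables[6.0]
        balanced = classify.balance_classes(table, seed=0)
        train, test = classify.split_train_test(balanced, 0.5, seed=1)
        return classify.evaluate_model(
            ModelSpec(Algorithm.RANDOM_FOREST, "all", 6.0, seed=0), train, test
        )

    def test_single_window_trace_gives_one_prediction(self, training_tables):
        rep = self._trained_report(training_tables)
        trace = AccelTrace(
            "t1", 25.0, datetime(2021, 6, 1, tzinfo=timezone.utc),
            np.tile([0.0, 0.0, 1.0], (150, 1)),
        )
        out = classify.annotate_deployment(trace, rep)
        assert len(out) == 1

    def test_trace_shorter_than_window_is_empty_with_warning(
        self, training_tables, caplog
    ):
        rep = self._trained_report(training_tables)
        trace = AccelTrace(
            "t2", 25.0, datetime(2021, 6, 1, tzinfo=timezone.utc),
            np.tile([0.0, 0.0, 1.0], (100, 1)),
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="kratkit.classify"):
            out = classify.annotate_deployment(trace, rep)
        assert out.empty
        assert any("shorter" in r.message for r in caplog.records)

    def test_motionless_trace_predicted_motionless(self, training_tables):
        rep = self._trained_report(training_tables)
        rng = np.random.default_rng(0)
        n = 150 * 40
        samples = np.tile([0.0, 0.0, 1.0], (n, 1)) + rng.normal(0, 0.02, (n, 3))
        trace = AccelTrace("t3", 25.0, datetime(2021, 6, 1, tzinfo=timezone.utc), samples)
        out = classify.annotate_deployment(trace, rep)
        assert (out["behavior"] == "motionless").mean() >= 0.99

    def test_predictions_deterministic(self, training_tables, deployment):
        rep = self._trained_report(training_tables)
        a = classify.annotate_deployment(deployment.trace, rep)
        b = classify.annotate_deployment(deployment.trace, rep)
        pd.testing.assert_frame_equal(a, b)
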