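"""Tests for splitting, grid search, metric computation and learning curves."""

import numpy as np
import pytest
from sklearn.model_selection import StratifiedKFold, cross_val_score

import eeglevels as el
from eeglevels.classify import (FittedModel, _make_pipeline, evaluate,
                                learning_curve, metrics_from_confusion, _roc)
from eeglevels.data import FeatureTable


def cohort_table(n_subjects=16, n_features=5, seed=0):
    """One row per subject-window: class pattern (0, 1, 1) per subject."""
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for s in range(n_subjects):
        for label in (0, 1, 1):
            rows.append(rng.standard_normal(n_features) + 2.5 * label)
            labels.append(label)
            groups.append(f"sub-{s:02d}")
    return FeatureTable("C", [f"f{i}" for i in range(n_features)],
                        np.array(rows), np.array(labels), np.array(groups))


class TestSplitData:
    def test_row_split_arithmetic(self):
        tab = cohort_table()
        train, test = el.split_data(tab, el.SplitPlan(grouping="row", seed=0))
        assert (train.n_rows, test.n_rows) == (36, 12)

    def test_subject_grouped_split_keeps_windows_together(self):
        tab = cohort_table()
        train, test = el.split_data(tab, el.SplitPlan(seed=0))
        train_subj, test_subj = set(train.groups), set(test.groups)
        assert len(test_subj) == 4 and len(train_subj) == 12
        assert not train_subj & test_subj
        # every test subject contributes all three windows
        for s in test_subj:
            assert (test.groups == s).sum() == 3

    def test_deterministic_and_seed_sensitive(self):
        tab = cohort_table()
        a1, _ = el.split_data(tab, el.SplitPlan(seed=5))
        a2, _ = el.split_data(tab, el.SplitPlan(seed=5))
        b, _ = el.split_data(tab, el.SplitPlan(seed=6))
        assert np.array_equal(a1.X, a2.X)
        assert not np.array_equal(a1.X, b.X)

    def test_single_subject_grouping_impossible(self):
        tab = cohort_table(n_subjects=1)
        with pytest.raises(ValueError):
            el.split_data(tab, el.SplitPlan(seed=0))


class TestGridSearchFit:
    def test_degenerate_grid_selects_that_point(self):
        tab = cohort_table()
        grid = [{"svc__kernel": ["linear"], "svc__C": [2.0]}]
        model = el.grid_search_fit(tab, grid, k=3, seed=0)
        assert model.best_params == {"svc__kernel": "linear", "svc__C": 2.0}

    def test_separable_data_reaches_perfect_training_accuracy(self):
        # a 6-sigma class shift in every feature is linearly separable
        rng = np.random.default_rng(0)
        X = np.vstack([rng.standard_normal((20, 2)),
                       rng.standard_normal((20, 2)) + 6.0])
        tab = FeatureTable("C", ["f0", "f1"], X,
                           np.array([0] * 20 + [1] * 20),
                           np.array([f"s{i}" for i in range(40)], dtype=object))
        model = el.grid_search_fit(tab, k=5, seed=0)
        assert (model.predict(tab) == tab.y).mean() == 1.0

    def test_cv_score_self_consistency(self):
        # the stored CV mean of the winner equals an independent re-run of
        # k-fold scoring with the same folds and hyper-parameters
        tab = cohort_table(seed=3)
        model = el.grid_search_fit(tab, k=5, seed=9)
        pipe = _make_pipeline("balanced")
        pipe.set_params(**model.best_params)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        scores = cross_val_score(pipe, tab.X, tab.y, cv=cv, scoring="accuracy")
        assert model.cv_best_mean_accuracy == pytest.approx(scores.mean(), abs=1e-12)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            el.grid_search_fit(cohort_table(), [], k=3, seed=0)


class _MockModel:
    """Fixed predictions/scores for metric-formula tests."""

    def __init__(self, feature_names, y_pred, scores):
        self.feature_names = feature_names
        self._y_pred = np.asarray(y_pred)
        self._scores = np.asarray(scores, dtype=float)

    def predict(self, table):
        return self._y_pred

    def decision_scores(self, table):
        return self._scores


class TestEvaluate:
    def test_metric_formulas_on_fixed_confusion_table(self):
        # TP=2, FP=1, FN=0, TN=1
        tab = FeatureTable("C", ["f"], np.zeros((4, 1)),
                           np.array([1, 1, 0, 0]), np.array(["a", "b", "c", "d"]))
        model = _MockModel(["f"], [1, 1, 1, 0], [2.0, 1.5, 0.5, -1.0])
        rep = evaluate(model, tab, "test")
        assert rep["precision"] == pytest.approx(2 / 3)
        assert rep["recall"] == pytest.approx(1.0)
        assert rep["f1"] == pytest.approx(0.8)
        assert rep["accuracy"] == pytest.approx(0.75)
        assert rep["confusion_matrix"] == [[1, 1], [0, 2]]

    def test_f1_is_harmonic_mean(self):
        m = metrics_from_confusion(tp=1, fp=1, fn=0, tn=0)
        assert m["precision"] == 0.5 and m["recall"] == 1.0
        assert m["f1"] == pytest.approx(2 / 3)

    def test_single_class_table_rejected(self):
        tab = FeatureTable("C", ["f"], np.zeros((3, 1)),
                           np.array([1, 1, 1]), np.array(["a", "b", "c"]))
        model = _MockModel(["f"], [1, 1, 1], [1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="single-class"):
            evaluate(model, tab, "test")

    def test_micro_equals_macro_for_balanced_symmetric_scores(self):
        y = np.array([0, 0, 1, 1])
        scores = np.array([-2.0, -1.0, 1.0, 2.0])
        roc = _roc(y, scores)
        assert roc["micro"]["auc"] == pytest.approx(roc["macro"]["auc"])
        assert roc["per_class"]["0"]["auc"] == pytest.approx(roc["per_class"]["1"]["auc"])

    def test_perfect_scores_give_unit_auc(self):
        roc = _roc(np.array([0, 1, 0, 1]), np.array([-1.0, 2.0, -0.5, 1.0]))
        assert roc["macro"]["auc"] == pytest.approx(1.0)


class TestLearningCurve:
    def test_full_size_matches_evaluate(self):
        tab = cohort_table(seed=4)
        train, test = el.split_data(tab, el.SplitPlan(seed=1))
        model = el.grid_search_fit(train, k=4, seed=1)
        rep = evaluate(model, test, "test")
        pts = learning_curve(train, test, model_params=model.best_params,
                             sizes=[train.n_rows], n_repeats=1, seed=1)
        assert pts[-1]["test_accuracy"] == pytest.approx(rep["accuracy"])

    def test_accuracy_trend_nonnegative_on_planted_effect(self):
        # with a weak planted shift, test accuracy should trend upward (or
        # stay flat) with training size in the majority of seeds
        from scipy.stats import spearmanr

        ok = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            rows, labels, groups = [], [], []
            for s in range(24):
                for label in (0, 1, 1):
                    rows.append(rng.standard_normal(4) + 0.8 * label)
                    labels.append(label)
                    groups.append(f"sub-{s:02d}")
            tab = FeatureTable("C", [f"f{i}" for i in range(4)], np.array(rows),
                               np.array(labels), np.array(groups))
            train, test = el.split_data(tab, el.SplitPlan(seed=seed))
            sizes = [8, 20, 36, train.n_rows]
            pts = learning_curve(train, test,
                                 model_params={"svc__kernel": "linear", "svc__C": 1.0},
                                 sizes=sizes, n_repeats=4, seed=seed)
            accs = [p["test_accuracy"] for p in pts if "test_accuracy" in p]
            rho = spearmanr(sizes[:len(accs)], accs).statistic
            ok += bool(np.isnan(rho) or rho >= 0)
        assert ok >= 3

    def test_sizes_must_be_increasing(self):
        tab = cohort_table()
        train, test = el.split_data(tab, el.SplitPlan(seed=0))
        with pytest.raises(ValueError, match="increasing"):
            learning_curve(train, test, sizes=[20, 10])
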