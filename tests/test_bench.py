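"""Classifier bench: fold dealing, CV evaluation, leakage canary, random
search, and consensus selection."""

import numpy as np
import pandas as pd
import pytest

from pwabs import stats
from pwabs.bench import (
    ClassifierBench,
    consensus_select,
    default_bench,
    evaluate_model,
    hyperparameter_search,
    kfold_split,
)


def linear_adapters():
    return [a for a in default_bench()
            if a.name in ("Linear Regression", "Logistic Regression standardized")]


@pytest.fixture
def separable():
    rng = np.random.default_rng(3)
    n = 30
    y = np.r_[np.ones(15, dtype=int), np.zeros(15, dtype=int)]
    X = rng.normal(size=(n, 6))
    X[:, 0] += 6 * y  # one hugely informative feature
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(6)]), y


class TestKFold:
    def test_fold_sizes(self):
        f35 = kfold_split(35, 5, 0)
        assert sorted(np.bincount(f35)) == [7] * 5
        f10 = kfold_split(10, 3, 0)
        assert sorted(np.bincount(f10)) == [3, 3, 4]

    def test_partition_properties(self, rng):
        folds = kfold_split(23, 4, 11)
        assert set(folds) == {0, 1, 2, 3}
        assert len(folds) == 23  # every subject in exactly one fold

    def test_deterministic_and_seed_sensitive(self):
        assert (kfold_split(20, 4, 7) == kfold_split(20, 4, 7)).all()
        assert not (kfold_split(20, 4, 7) == kfold_split(20, 4, 8)).all()

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            kfold_split(5, 6, 0)


class TestEvaluateModel:
    def test_separable_data_perfect_auc(self, separable):
        X, y = separable
        folds = kfold_split(len(y), 5, 0)
        for adapter in linear_adapters():
            rep = evaluate_model(adapter, X, y, folds)
            assert rep.mean_roc_auc == pytest.approx(1.0)

    def test_shuffled_labels_chance_auc(self, separable, rng):
        X, _ = separable
        y = rng.permutation(np.r_[np.ones(15, dtype=int), np.zeros(15, dtype=int)])
        folds = kfold_split(len(y), 5, 1)
        rep = evaluate_model(linear_adapters()[0], X, y, folds)
        assert abs(rep.mean_roc_auc - 0.5) < 0.25

    def test_metrics_consistent_with_stats_recomputation(self, separable):
        X, y = separable
        folds = kfold_split(len(y), 5, 0)
        rep = evaluate_model(linear_adapters()[1], X, y, folds)
        for f, (idx, scores) in enumerate(rep.fold_scores):
            assert rep.fold_metrics.loc[f, "roc_auc"] == pytest.approx(
                stats.roc_auc(scores, y[idx]))
            assert rep.fold_metrics.loc[f, "pr_auc"] == pytest.approx(
                stats.pr_auc(scores, y[idx]))

    def test_leak_canary(self, rng):
        """A feature carrying the label only on one fold's *test* subjects
        must not help: per-fold scaling and fitting see training data only,
        so that fold's AUC stays near chance."""
        n, k = 40, 4
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        folds = kfold_split(n, k, 2)
        aucs = []
        for f in range(k):
            X = rng.normal(size=(n, 3))
            test = folds == f
            X[test, 0] = y[test] * 10.0  # signal present only in the held-out fold
            rep = evaluate_model(linear_adapters()[1], pd.DataFrame(X), y, folds)
            aucs.append(rep.fold_metrics.loc[f, "roc_auc"])
        assert abs(np.mean(aucs) - 0.5) < 0.15

    def test_importance_vector_shape(self, separable):
        X, y = separable
        folds = kfold_split(len(y), 5, 0)
        for adapter in default_bench():
            rep = evaluate_model(adapter, X, y, folds)
            assert len(rep.importances) == X.shape[1]
            assert (rep.importances >= 0).all()

    def test_informative_feature_tops_importance(self, separable):
        X, y = separable
        folds = kfold_split(len(y), 5, 0)
        rep = evaluate_model(linear_adapters()[1], X, y, folds)
        assert rep.importances.idxmax() == "f0"


class TestHyperparameterSearch:
    def test_budget_one_returns_default(self, separable):
        X, y = separable
        adapter = [a for a in default_bench() if a.name == "Ridge Regression"][0]
        params, _ = hyperparameter_search(adapter, X, y, budget=1, seed=0)
        assert params == adapter.defaults

    def test_best_beats_default(self, separable):
        X, y = separable
        adapter = [a for a in default_bench() if a.name == "Lasso Regression"][0]
        folds = kfold_split(len(y), 5, 0)
        _, best_score = hyperparameter_search(adapter, X, y, budget=4, seed=0, folds=folds)
        default_score = evaluate_model(adapter, X, y, folds).mean_roc_auc
        assert best_score >= default_score - 1e-12


def _report(name, auc, importances, features):
    from pwabs.bench import CVReport

    fm = pd.DataFrame({m: [auc] * 2 for m in
                       ("roc_auc", "pr_auc", "accuracy", "precision", "recall", "f1")})
    return CVReport(name, fm, np.zeros(4, dtype=int), 0,
                    pd.Series(importances, index=features))


class TestConsensus:
    features = [f"g{i}" for i in range(20)]

    def test_identical_top_lists_selected(self):
        imp = np.r_[np.arange(20, 0, -1)].astype(float)
        reports = [_report(f"m{i}", 0.99, imp, self.features) for i in range(4)]
        res = consensus_select(reports, auc_gate=0.96, top_k=10, min_models=2)
        assert res.selected == self.features[:10]
        assert res.qualifying == [f"m{i}" for i in range(4)]

    def test_gate_excludes_low_auc_model(self):
        imp_a = np.r_[np.ones(10), np.zeros(10)]
        imp_b = np.r_[np.zeros(10), np.ones(10)]
        reports = [_report("good", 0.99, imp_a, self.features),
                   _report("bad", 0.90, imp_b, self.features)]
        res = consensus_select(reports, auc_gate=0.96, top_k=10, min_models=1)
        assert res.qualifying == ["good"]
        assert res.selected == self.features[:10]

    def test_min_models_threshold(self):
        imp_a = np.r_[np.ones(10), np.zeros(10)]
        reports = [_report("m1", 0.99, imp_a, self.features),
                   _report("m2", 0.99, imp_a, self.features)]
        res = consensus_select(reports, auc_gate=0.96, top_k=10, min_models=3)
        assert res.selected == []

    def test_no_qualifying_model_warns_empty(self):
        reports = [_report("m1", 0.5, np.ones(20), self.features)]
        with pytest.warns(UserWarning, match="gate"):
            res = consensus_select(reports, auc_gate=0.96)
        assert res.selected == [] and res.qualifying == []

    def test_order_invariance(self, rng):
        reports = [_report(f"m{i}", 0.97 + i / 100, rng.uniform(size=20), self.features)
                   for i in range(5)]
        a = consensus_select(reports)
        b = consensus_select(reports[::-1])
        assert a.selected == b.selected and a.qualifying == b.qualifying


class TestBenchEndToEnd:
    def test_strong_signal_recovery(self, strong_signal_cohort):
        au, y, truth = strong_signal_cohort
        res = ClassifierBench(au.values, y).fit(k=5, seed=42)
        assert res.best.mean_roc_auc >= 0.9
        cons = res.consensus(auc_gate=0.96, top_k=10, min_models=2)
        assert len(set(cons.selected) & truth.elevated_ad) >= 6

    def test_summary_shape(self, strong_signal_cohort):
        au, y, _ = strong_signal_cohort
        res = ClassifierBench(au.values, y,
                              adapters=linear_adapters()).fit(k=5, seed=0)
        table = res.summary()
        assert list(table.columns) == ["AUC", "PR-AUC", "Accuracy", "Precision",
                                       "Recall", "f1-score"]
        assert len(table) == 2

    def test_single_class_labels_rejected(self):
        with pytest.raises(ValueError):
            ClassifierBench(pd.DataFrame(np.ones((4, 2))), [1, 1, 1, 1])
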