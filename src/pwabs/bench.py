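"""Cross-validated classifier bench with feature-importance consensus.

Runs a fixed bench of 14 classifier configurations (linear, tree, kernel and
Bayes families, mirroring the published comparison table) on the binary
task — by default AD versus everyone else — under k-fold cross-validation,
computes six metrics per model via :mod:`pwabs.stats`, extracts per-model
feature importances (absolute coefficients for linear models, split-gain
importances for tree ensembles), and applies AUC-gated top-k consensus
feature selection: keep models whose mean ROC-AUC beats the gate, take each
one's top-k features by importance, and select features highlighted by at
least ``min_models`` of them.

Adapters are backed by scikit-learn estimators; the folds, scaling (fit on
the training portion of each fold only), metrics, importances and consensus
are computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats

__all__ = [
    "ModelAdapter",
    "CVReport",
    "ConsensusResult",
    "kfold_split",
    "evaluate_model",
    "hyperparameter_search",
    "consensus_select",
    "default_bench",
    "ClassifierBench",
    "BenchResults",
]

log = logging.getLogger(__name__)

METRICS = ("roc_auc", "pr_auc", "accuracy", "precision", "recall", "f1")


def kfold_split(n_subjects: int, k: int, seed: int) -> np.ndarray:
    """Shuffled k-fold assignment: fold label per subject, sizes differ by <= 1."""
    if not 2 <= k <= n_subjects:
        raise ValueError(f"need 2 <= k <= n ({k} vs {n_subjects})")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_subjects)
    folds = np.empty(n_subjects, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        folds[chunk] = f
    return folds


@dataclass
class ModelAdapter:
    """One bench entry: estimator factory plus scaling and importance contract."""

    name: str
    family: str  # linear | tree | kernel | bayes
    scaling: str  # none | minmax | zscore
    factory: callable  # (**params) -> estimator
    param_space: dict = field(default_factory=dict)  # name -> list of candidates
    defaults: dict = field(default_factory=dict)

    def build(self, params=None):
        return self.factory(**{**self.defaults, **(params or {})})

    def importance(self, fitted) -> np.ndarray:
        if hasattr(fitted, "coef_"):
            coef = np.asarray(fitted.coef_, dtype=float)
            return np.abs(coef).reshape(-1)
        if hasattr(fitted, "feature_importances_"):
            return np.asarray(fitted.feature_importances_, dtype=float)
        if hasattr(fitted, "theta_"):  # Gaussian naive Bayes: class-mean separation
            theta = np.asarray(fitted.theta_)
            sigma = np.sqrt(np.asarray(fitted.var_))
            return np.abs(theta[1] - theta[0]) / np.where(sigma.mean(0) > 0, sigma.mean(0), 1.0)
        raise AttributeError(f"{self.name}: no importance contract")


def _scale_fit(X: np.ndarray, how: str):
    if how == "none":
        return ("none",)
    if how == "minmax":
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        return ("minmax", lo, span)
    if how == "zscore":
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        return ("zscore", mu, sd)
    raise ValueError(f"unknown scaling {how!r}")


def _scale_apply(X: np.ndarray, params) -> np.ndarray:
    kind = params[0]
    if kind == "none":
        return X
    a, b = params[1], params[2]
    return (X - a) / b


def _scores_from(fitted, X: np.ndarray) -> np.ndarray:
    """Continuous scores in [0, 1]: probabilities when available, otherwise
    min-max-rescaled decision values / regression predictions."""
    if hasattr(fitted, "predict_proba"):
        return fitted.predict_proba(X)[:, 1]
    raw = fitted.decision_function(X) if hasattr(fitted, "decision_function") else fitted.predict(X)
    raw = np.asarray(raw, dtype=float)
    lo, hi = raw.min(), raw.max()
    return (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)


@dataclass
class CVReport:
    """Cross-validation outcome for one bench model."""

    name: str
    fold_metrics: pd.DataFrame  # rows = folds, columns = METRICS
    folds: np.ndarray
    seed: int
    importances: pd.Series  # index = feature names
    fold_scores: list = field(default_factory=list, repr=False)  # (test_idx, scores) per fold

    @property
    def mean_metrics(self) -> pd.Series:
        return self.fold_metrics.mean(axis=0, skipna=True)

    @property
    def mean_roc_auc(self) -> float:
        return float(self.mean_metrics["roc_auc"])


def _valid_folds(y: np.ndarray, n: int, k: int, seed: int) -> tuple[np.ndarray, int]:
    """Fold assignment whose every training portion contains both classes."""
    s = seed
    for _ in range(100):
        folds = kfold_split(n, k, s)
        ok = all(len(np.unique(y[folds != f])) == 2 for f in range(k))
        if ok:
            if s != seed:
                log.info("re-drew folds at seed %d (training fold lacked a class)", s)
            return folds, s
        s += 1
    raise ValueError("could not find folds with both classes in every training split")


def evaluate_model(adapter: ModelAdapter, X, y, folds, seed: int = 0,
                   params=None, importance_mode: str = "full") -> CVReport:
    """Fit/evaluate one adapter under pre-assigned folds.

    Scaling statistics are computed on each fold's training portion only.
    A fold where the estimator fails is logged, recorded as NaN, and
    excluded from the means.  The reported importance vector comes from a
    final fit on all data (``importance_mode="full"``, the default) or from
    the mean of per-fold importances (``"per-fold"``).
    """
    Xdf = pd.DataFrame(X)
    feature_names = list(Xdf.columns)
    Xa = Xdf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=int)
    folds = np.asarray(folds)
    k = int(folds.max()) + 1
    rows = []
    fold_scores = []
    per_fold_imp = []
    for f in range(k):
        test = folds == f
        train = ~test
        sc = _scale_fit(Xa[train], adapter.scaling)
        Xtr, Xte = _scale_apply(Xa[train], sc), _scale_apply(Xa[test], sc)
        est = adapter.build(params)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                est.fit(Xtr, y[train])
            scores = _scores_from(est, Xte)
        except Exception as exc:  # convergence/degenerate-fold failures
            log.warning("%s fold %d failed: %s", adapter.name, f, exc)
            rows.append({m: np.nan for m in METRICS})
            fold_scores.append((np.where(test)[0], None))
            continue
        yt = y[test]
        row = {}
        try:
            row["roc_auc"] = stats.roc_auc(scores, yt)
            row["pr_auc"] = stats.pr_auc(scores, yt)
        except ValueError:  # single-class test fold
            row["roc_auc"] = np.nan
            row["pr_auc"] = np.nan
        tm = stats.threshold_metrics(scores, yt)
        row.update(accuracy=tm.accuracy, precision=tm.precision, recall=tm.recall, f1=tm.f1)
        rows.append(row)
        fold_scores.append((np.where(test)[0], scores))
        try:
            per_fold_imp.append(adapter.importance(est))
        except AttributeError:
            pass
    fold_metrics = pd.DataFrame(rows, columns=list(METRICS))

    if importance_mode == "per-fold" and per_fold_imp:
        imp = np.mean(per_fold_imp, axis=0)
    else:
        sc = _scale_fit(Xa, adapter.scaling)
        est = adapter.build(params)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(_scale_apply(Xa, sc), y)
        imp = adapter.importance(est)
    importances = pd.Series(np.asarray(imp, dtype=float), index=feature_names, name=adapter.name)
    return CVReport(adapter.name, fold_metrics, folds, seed, importances, fold_scores)


def hyperparameter_search(adapter: ModelAdapter, X, y, budget: int, seed: int,
                          folds=None) -> tuple[dict, float]:
    """Bounded random search over the adapter's parameter space by mean CV
    ROC-AUC.  The default configuration is always in the candidate sample,
    so the winner never scores below it.  Returns (best_params, best_score)."""
    if budget < 1:
        raise ValueError("budget must be >= 1")
    y = np.asarray(y, dtype=int)
    n = len(y)
    if folds is None:
        folds, _ = _valid_folds(y, n, min(5, n), seed)
    rng = np.random.default_rng(seed)
    candidates = [dict(adapter.defaults)]
    space = {k: list(v) for k, v in adapter.param_space.items()}
    while len(candidates) < budget:
        cand = {k: v[int(rng.integers(len(v)))] for k, v in space.items()}
        candidates.append(cand)
    best, best_score = candidates[0], -np.inf
    for cand in candidates[:budget]:
        rep = evaluate_model(adapter, X, y, folds, seed, params=cand)
        score = rep.mean_roc_auc
        if np.isfinite(score) and score > best_score:
            best, best_score = cand, score
    return best, float(best_score)


@dataclass
class ConsensusResult:
    """AUC-gated top-k consensus selection outcome."""

    qualifying: list  # model names with mean ROC-AUC > gate
    top_features: dict  # model name -> ordered top-k feature list
    counts: pd.Series  # feature -> number of qualifying top-k lists containing it
    selected: list  # features with count >= min_models, stable feature order
    auc_gate: float
    top_k: int
    min_models: int

    def to_dict(self) -> dict:
        return {
            "qualifying": self.qualifying,
            "top_features": self.top_features,
            "counts": {str(k): int(v) for k, v in self.counts.items()},
            "selected": self.selected,
            "auc_gate": self.auc_gate,
            "top_k": self.top_k,
            "min_models": self.min_models,
        }


def consensus_select(reports, auc_gate: float = 0.96, top_k: int = 10,
                     min_models: int = 2) -> ConsensusResult:
    """Select features highlighted by >= ``min_models`` of the qualifying
    models' top-k importance lists.  Importance ties break by stable feature
    order; no model passing the gate yields an empty (warned) result."""
    if not reports:
        raise ValueError("need at least one CV report")
    reports = sorted(reports, key=lambda r: r.name)  # order-invariant output
    feature_order = list(reports[0].importances.index)
    qualifying = [r for r in reports if np.isfinite(r.mean_roc_auc) and r.mean_roc_auc > auc_gate]
    if not qualifying:
        warnings.warn(f"no model exceeds the ROC-AUC gate {auc_gate}; empty consensus",
                      stacklevel=2)
    top_features = {}
    for r in qualifying:
        imp = r.importances
        order = sorted(range(len(feature_order)), key=lambda i: (-imp.iloc[i], i))
        top_features[r.name] = [feature_order[i] for i in order[:top_k]]
    counts = pd.Series(0, index=feature_order, dtype=int)
    for feats in top_features.values():
        counts[feats] += 1
    selected = [f for f in feature_order if counts[f] >= min_models] if qualifying else []
    return ConsensusResult([r.name for r in qualifying], top_features, counts,
                           selected, auc_gate, top_k, min_models)


def default_bench() -> list[ModelAdapter]:
    """The 14-model bench: linear regressors, regularized and logistic
    variants, linear SVMs, tree ensembles (three gradient-boosting
    configurations standing in for the XGBoost/LightGBM/CatBoost family),
    a decision tree and Gaussian naive Bayes."""
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import Lasso, LinearRegression, LogisticRegression, Ridge
    from sklearn.naive_bayes import GaussianNB
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    return [
        ModelAdapter("Linear Regression", "linear", "none", LinearRegression),
        ModelAdapter("Lasso Regression", "linear", "zscore", Lasso,
                     {"alpha": [0.01, 0.1, 0.5, 1.0]}, {"alpha": 0.1}),
        ModelAdapter("Ridge Regression", "linear", "zscore", Ridge,
                     {"alpha": [0.1, 1.0, 10.0]}, {"alpha": 1.0}),
        ModelAdapter("Logistic Regression normalized", "linear", "minmax", LogisticRegression,
                     {"C": [0.1, 1.0, 10.0]}, {"C": 1.0, "max_iter": 2000}),
        ModelAdapter("Logistic Regression standardized", "linear", "zscore", LogisticRegression,
                     {"C": [0.1, 1.0, 10.0]}, {"C": 1.0, "max_iter": 2000}),
        ModelAdapter("SVM normalized", "kernel", "minmax", SVC,
                     {"C": [0.1, 1.0, 10.0]}, {"kernel": "linear", "C": 1.0}),
        ModelAdapter("SVM standardized", "kernel", "zscore", SVC,
                     {"C": [0.1, 1.0, 10.0]}, {"kernel": "linear", "C": 1.0}),
        ModelAdapter("Random Forest", "tree", "none", RandomForestClassifier,
                     {"n_estimators": [100, 200], "max_depth": [None, 3, 5]},
                     {"n_estimators": 200, "random_state": 0}),
        ModelAdapter("Gradient Boosting (xgboost-style)", "tree", "none", GradientBoostingClassifier,
                     {"learning_rate": [0.05, 0.1, 0.3], "max_depth": [2, 3]},
                     {"n_estimators": 100, "subsample": 0.8, "max_depth": 3, "random_state": 0}),
        ModelAdapter("Gradient Boosting (lightgbm-style)", "tree", "none", GradientBoostingClassifier,
                     {"learning_rate": [0.05, 0.1, 0.3]},
                     {"n_estimators": 100, "max_depth": 2, "max_features": "sqrt", "random_state": 0}),
        ModelAdapter("Gradient Boosting (catboost-style)", "tree", "none", GradientBoostingClassifier,
                     {"learning_rate": [0.02, 0.05, 0.1]},
                     {"n_estimators": 200, "learning_rate": 0.05, "max_depth": 3, "random_state": 0}),
        ModelAdapter("Decision Tree", "tree", "none", DecisionTreeClassifier,
                     {"max_depth": [None, 2, 3, 5]}, {"random_state": 0}),
        ModelAdapter("Gradient Boosting Machine", "tree", "none", GradientBoostingClassifier,
                     {"learning_rate": [0.05, 0.1, 0.3]}, {"n_estimators": 100, "random_state": 0}),
        ModelAdapter("Naive Bayes", "bayes", "none", GaussianNB),
    ]


@dataclass
class BenchResults:
    """All CV reports plus the consensus machinery and a Table-1-shaped view."""

    reports: list
    folds: np.ndarray
    seed: int
    task: str

    def summary(self) -> pd.DataFrame:
        rows = {r.name: r.mean_metrics for r in self.reports}
        df = pd.DataFrame(rows).T[list(METRICS)]
        df.columns = ["AUC", "PR-AUC", "Accuracy", "Precision", "Recall", "f1-score"]
        return df.round(3)

    def report(self, name: str) -> CVReport:
        for r in self.reports:
            if r.name == name:
                return r
        raise KeyError(name)

    @property
    def best(self) -> CVReport:
        return max(self.reports, key=lambda r: (np.nan_to_num(r.mean_roc_auc, nan=-1.0)))

    def consensus(self, auc_gate: float = 0.96, top_k: int = 10,
                  min_models: int = 2) -> ConsensusResult:
        return consensus_select(self.reports, auc_gate, top_k, min_models)

    def importances_frame(self) -> pd.DataFrame:
        return pd.DataFrame({r.name: r.importances for r in self.reports})


class ClassifierBench:
    """Binary-classification bench over an AU feature matrix.

    Parameters
    ----------
    X : DataFrame
        Subjects x features (typically the differentially elevated panel).
    y : array-like
        Binary labels (1 = case). Use :meth:`from_diagnosis` to build the
        AD-vs-rest or DLB-vs-rest task from a diagnosis column.
    adapters : list of ModelAdapter, optional
        Defaults to the 14-model bench.
    """

    def __init__(self, X, y, adapters=None, task: str = "ad-vs-rest"):
        self.X = pd.DataFrame(X)
        self.y = np.asarray(y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y length mismatch")
        if set(np.unique(self.y)) != {0, 1}:
            raise ValueError("y must contain both classes, coded 0/1")
        self.adapters = adapters if adapters is not None else default_bench()
        self.task = task

    @classmethod
    def from_diagnosis(cls, au, diagnosis, case: str = "AD", features=None, **kw):
        X = au.values if hasattr(au, "values") and not isinstance(au, pd.DataFrame) else pd.DataFrame(au)
        if features is not None:
            X = X[list(features)]
        diagnosis = pd.Series(diagnosis).reindex(X.index)
        y = (diagnosis == case).astype(int).to_numpy()
        return cls(X, y, task=f"{case.lower()}-vs-rest", **kw)

    def fit(self, k: int = 5, seed: int = 0, tune_budget: int = 0,
            importance_mode: str = "full") -> BenchResults:
        folds, used_seed = _valid_folds(self.y, len(self.y), k, seed)
        reports = []
        for adapter in self.adapters:
            params = None
            if tune_budget > 0 and adapter.param_space:
                params, _ = hyperparameter_search(adapter, self.X, self.y,
                                                  tune_budget, seed, folds)
            reports.append(evaluate_model(adapter, self.X, self.y, folds,
                                          used_seed, params, importance_mode))
        return BenchResults(reports, folds, used_seed, self.task)
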