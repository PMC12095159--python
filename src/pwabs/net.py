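"""Three-class feed-forward network (CNI / AD / DLB) in plain numpy.

Architecture and training recipe: two fully connected hidden layers of 8 and
4 rectified units, a 3-logit output layer with softmax cross-entropy loss,
Adam at learning rate 0.001, 150 epochs of shuffled minibatches of 16, and
3-fold cross-validation with per-training-fold feature standardization.
Weights initialize from a seeded uniform in +-sqrt(6/(fan_in+fan_out));
biases start at zero.  Single-threaded numpy makes runs bit-reproducible
for a fixed seed.

Class encoding is fixed: class 1 = CNI, class 2 = AD, class 3 = DLB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import stats
from .bench import kfold_split

__all__ = ["NetConfig", "NetReport", "DementiaNet", "CLASS_ORDER",
           "net_forward", "net_train", "net_evaluate", "init_params"]

log = logging.getLogger(__name__)

CLASS_ORDER = ("CNI", "AD", "DLB")  # class 1, 2, 3


@dataclass(frozen=True)
class NetConfig:
    """Hyperparameters of the 3-class net (defaults are the full recipe)."""

    input_dim: int
    hidden: tuple = (8, 4)
    n_classes: int = 3
    learning_rate: float = 0.001
    epochs: int = 150
    batch_size: int = 16
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden):
            raise ValueError("hidden sizes must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


def init_params(config: NetConfig) -> list:
    """Seeded Glorot-uniform weights, zero biases; one (W, b) pair per layer."""
    rng = np.random.default_rng(config.seed)
    dims = (config.input_dim, *config.hidden, config.n_classes)
    params = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        params.append([rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                       np.zeros(fan_out)])
    return params


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def net_forward(params, x) -> np.ndarray:
    """Class probabilities for one feature vector or a batch."""
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != params[0][0].shape[0]:
        raise ValueError(f"input dim {a.shape[1]} != expected {params[0][0].shape[0]}")
    for W, b in params[:-1]:
        a = np.maximum(a @ W + b, 0.0)
    W, b = params[-1]
    probs = _softmax(a @ W + b)
    return probs[0] if np.asarray(x).ndim == 1 else probs


def _forward_cache(params, X):
    acts = [X]
    a = X
    for W, b in params[:-1]:
        a = np.maximum(a @ W + b, 0.0)
        acts.append(a)
    W, b = params[-1]
    return acts, _softmax(a @ W + b)


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))


def _backward(params, acts, probs, y):
    n = len(y)
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta /= n
    grads = []
    for layer in range(len(params) - 1, -1, -1):
        W, _ = params[layer]
        grads.append([acts[layer].T @ delta, delta.sum(axis=0)])
        if layer > 0:
            delta = (delta @ W.T) * (acts[layer] > 0)
    return grads[::-1]


def _train_one(X, y, config: NetConfig, X_val=None, y_val=None):
    """Adam on softmax cross-entropy; returns params and per-epoch losses."""
    params = init_params(config)
    m = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
    v = [[np.zeros_like(W), np.zeros_like(b)] for W, b in params]
    rng = np.random.default_rng(config.seed + 1)
    t = 0
    train_loss, val_loss = [], []
    for _ in range(config.epochs):
        order = rng.permutation(len(y))
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            acts, probs = _forward_cache(params, X[idx])
            grads = _backward(params, acts, probs, y[idx])
            t += 1
            for layer in range(len(params)):
                for slot in range(2):
                    g = grads[layer][slot]
                    m[layer][slot] = config.beta1 * m[layer][slot] + (1 - config.beta1) * g
                    v[layer][slot] = config.beta2 * v[layer][slot] + (1 - config.beta2) * g * g
                    mhat = m[layer][slot] / (1 - config.beta1**t)
                    vhat = v[layer][slot] / (1 - config.beta2**t)
                    params[layer][slot] = params[layer][slot] - config.learning_rate * mhat / (
                        np.sqrt(vhat) + config.eps
                    )
        train_loss.append(_cross_entropy(_forward_cache(params, X)[1], y))
        if X_val is not None:
            val_loss.append(_cross_entropy(_forward_cache(params, X_val)[1], y_val))
    return params, train_loss, val_loss


@dataclass
class NetReport:
    """Cross-validated evaluation of the 3-class net."""

    loss_curves: pd.DataFrame  # fold, epoch, train_loss, val_loss
    confusion: np.ndarray  # pooled over folds, rows = true class
    fold_confusions: list
    class_metrics: pd.DataFrame  # per class: roc_auc, pr_auc, precision, recall, f1, n
    fold_models: list = field(repr=False, default_factory=list)
    folds: np.ndarray = None
    seed: int = 0

    @property
    def accuracy(self) -> float:
        """Pooled accuracy over all held-out predictions."""
        return float(np.trace(self.confusion) / self.confusion.sum())

    @property
    def macro_accuracy(self) -> float:
        """Balanced accuracy: mean per-class recall, robust to the cohort's
        class imbalance (chance level is 1/n_classes)."""
        row_sums = self.confusion.sum(axis=1)
        present = row_sums > 0
        recalls = np.diag(self.confusion)[present] / row_sums[present]
        return float(recalls.mean())

    def summary(self) -> str:
        lines = [
            f"3-class net: {len(self.fold_confusions)}-fold CV, pooled accuracy "
            f"{self.accuracy:.3f}, balanced accuracy {self.macro_accuracy:.3f}",
            "per-class one-vs-rest metrics:",
            self.class_metrics.round(3).to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "fold_confusions": [c.tolist() for c in self.fold_confusions],
            "class_metrics": self.class_metrics.to_dict(orient="index"),
            "accuracy": self.accuracy,
            "macro_accuracy": self.macro_accuracy,
            "seed": int(self.seed),
        }


def _confusion(y_true, y_pred, n_classes):
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t_, p_ in zip(y_true, y_pred):
        cm[t_, p_] += 1
    return cm


def net_evaluate(probs: np.ndarray, y: np.ndarray, class_names=CLASS_ORDER):
    """Confusion at argmax plus per-class one-vs-rest ROC/PR and threshold
    metrics from softmax probabilities."""
    pred = probs.argmax(axis=1)
    n_classes = probs.shape[1]
    cm = _confusion(y, pred, n_classes)
    rows = {}
    for c in range(n_classes):
        bin_y = (y == c).astype(int)
        row = {"n": int(bin_y.sum())}
        try:
            row["roc_auc"] = stats.roc_auc(probs[:, c], bin_y)
            row["pr_auc"] = stats.pr_auc(probs[:, c], bin_y)
        except ValueError:
            row["roc_auc"] = np.nan
            row["pr_auc"] = np.nan
        tp = int(((pred == c) & (y == c)).sum())
        fp = int(((pred == c) & (y != c)).sum())
        fn = int(((pred != c) & (y == c)).sum())
        row["precision"] = tp / (tp + fp) if tp + fp else 0.0
        row["recall"] = tp / (tp + fn) if tp + fn else 0.0
        pr, rc = row["precision"], row["recall"]
        row["f1"] = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
        rows[class_names[c]] = row
    return cm, pd.DataFrame(rows).T


def net_train(X, y, config: NetConfig, folds=None, k: int = 3, seed: int = 0) -> NetReport:
    """Train and evaluate the net under k-fold (default 3) cross-validation.

    ``y`` may be integer classes (0=CNI, 1=AD, 2=DLB) or diagnosis strings.
    Features are standardized on each fold's training portion.  Folds whose
    training split misses a class are re-dealt at an incremented seed.
    """
    Xa = pd.DataFrame(X).to_numpy(dtype=float)
    y = np.asarray(y)
    if y.dtype.kind in "UO":
        lut = {name: i for i, name in enumerate(CLASS_ORDER)}
        y = np.array([lut[str(v)] for v in y])
    y = y.astype(int)
    n = len(y)
    n_classes = int(config.n_classes)
    if folds is None:
        s = seed
        for _ in range(100):
            folds = kfold_split(n, k, s)
            if all(len(np.unique(y[folds != f])) == n_classes for f in range(k)):
                if s != seed:
                    log.info("re-drew net folds at seed %d", s)
                break
            s += 1
        else:
            raise ValueError("could not deal folds with all classes in training")
    folds = np.asarray(folds)
    k = int(folds.max()) + 1

    curves = []
    fold_models = []
    fold_cms = []
    pooled_probs = np.zeros((n, n_classes))
    for f in range(k):
        test = folds == f
        train = ~test
        mu, sd = Xa[train].mean(0), Xa[train].std(0)
        sd = np.where(sd > 0, sd, 1.0)
        Xtr, Xte = (Xa[train] - mu) / sd, (Xa[test] - mu) / sd
        cfg = replace(config, seed=config.seed + f)
        params, tl, vl = _train_one(Xtr, y[train], cfg, Xte, y[test])
        for e, (a, b) in enumerate(zip(tl, vl), start=1):
            curves.append((f, e, a, b))
        probs = _forward_cache(params, Xte)[1]
        pooled_probs[test] = probs
        cm, _ = net_evaluate(probs, y[test])
        fold_cms.append(cm)
        fold_models.append((params, mu, sd))
    pooled_cm, class_metrics = net_evaluate(pooled_probs, y)
    loss_curves = pd.DataFrame(curves, columns=["fold", "epoch", "train_loss", "val_loss"])
    return NetReport(loss_curves, pooled_cm, fold_cms, class_metrics, fold_models, folds, seed)


class DementiaNet:
    """Model wrapper: 3-class net over a selected-feature AU matrix.

    ``DementiaNet(X, diagnosis).fit()`` runs the full published recipe
    (8 -> 4 hidden units, Adam lr 0.001, 150 epochs, batch 16, 3-fold CV)
    and returns a :class:`NetReport`.
    """

    def __init__(self, X, y, config: NetConfig | None = None):
        self.X = pd.DataFrame(X)
        self.y = y
        self.config = config or NetConfig(input_dim=self.X.shape[1])
        if self.config.input_dim != self.X.shape[1]:
            raise ValueError("config.input_dim does not match X")

    def fit(self, k: int = 3, seed: int = 0) -> NetReport:
        return net_train(self.X, self.y, self.config, k=k, seed=seed)
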