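"""Statistical primitives used throughout the PWAbS analysis.

Self-contained implementations of the nonparametric tests and classification
metrics the screening pipeline relies on: Mann-Whitney U (exact by dynamic
programming for small groups, normal approximation with tie and continuity
correction otherwise), Spearman rank correlation, Fisher's exact 2x2 test,
ROC-AUC and average-precision PR-AUC, threshold classification metrics, and
ordinary least squares with per-coefficient t tests.

SciPy is used only for distribution functions (normal/t CDFs, log-gamma);
the test statistics and their null distributions are computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, ndtr
from scipy.stats import t as t_dist

__all__ = [
    "TestResult",
    "CorrelationResult",
    "ThresholdMetrics",
    "OLSResult",
    "CollinearityError",
    "mann_whitney_u",
    "spearman",
    "fisher_exact_2x2",
    "roc_auc",
    "pr_auc",
    "threshold_metrics",
    "ols_fit",
    "benjamini_hochberg",
    "rankdata",
]

# exact Mann-Whitney used when the smaller group is at most this size and
# there are no ties across the pooled sample
EXACT_CUTOFF = 8


class CollinearityError(ValueError):
    """Design matrix is rank deficient; carries the offending column indices."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; dependent columns: {self.columns}")


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-sample or contingency test."""

    statistic: float
    p_value: float
    method: str  # "exact" | "approximate"
    n1: int
    n2: int

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "statistic": float(self.statistic),
            "p_value": float(self.p_value),
            "method": self.method,
            "n1": self.n1,
            "n2": self.n2,
        }


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman correlation; ``undefined`` flags a constant input vector."""

    rho: float
    p_value: float
    n: int
    undefined: bool = False

    def __iter__(self):  # allow ``rho, p = spearman(x, y)``
        return iter((self.rho, self.p_value))


@dataclass(frozen=True)
class ThresholdMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    no_positive_predictions: bool = False

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def rankdata(a) -> np.ndarray:
    """Mid-ranks (ties share the average rank), 1-based."""
    a = np.asarray(a, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(a.size, dtype=float)
    sa = a[order]
    i = 0
    while i < a.size:
        j = i
        while j + 1 < a.size and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _exact_u_cdf(n1: int, n2: int, u: float) -> tuple[float, float]:
    """P(U <= u) and P(U >= u) under the exact tie-free null.

    Counts rank subsets by dynamic programming: f[j, s] = number of ways to
    choose j of the ranks 1..i with rank-sum s. U = ranksum - j(j+1)/2.
    """
    n = n1 + n2
    max_u = n1 * n2
    # f[j, u'] over "reduced" sums: choosing j items from 1..i contributes
    # sum - j(j+1)/2 in [0, j*(i-j)]; iterate items 0-based contribution.
    f = np.zeros((n1 + 1, max_u + 1), dtype=float)
    f[0, 0] = 1.0
    for i in range(1, n + 1):
        # adding rank i to a (j-1)-subset of ranks < i adds (i - j) to U
        for j in range(min(i, n1), 0, -1):
            add = i - j
            if add > 0:
                f[j, add:] += f[j - 1, : max_u + 1 - add]
            else:
                f[j, :] += f[j - 1, :]
    dist = f[n1]
    total = dist.sum()
    uu = int(np.floor(u + 1e-9))
    cdf = dist[: uu + 1].sum() / total
    sf = dist[int(np.ceil(u - 1e-9)) :].sum() / total
    return cdf, sf


def mann_whitney_u(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney U test.

    U counts pairs with x_i > y_j plus half of the tied pairs.  The exact
    null distribution (full enumeration over label assignments, computed by
    DP) is used when the smaller group has at most ``EXACT_CUTOFF``
    observations and the pooled sample is tie-free; otherwise the normal
    approximation with tie correction and continuity correction applies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires non-empty samples")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0  # = #(x>y) + 0.5*ties

    has_ties = np.unique(pooled).size < pooled.size
    if min(n1, n2) <= EXACT_CUTOFF and not has_ties:
        cdf, sf = _exact_u_cdf(n1, n2, u)
        if alternative == "greater":
            p = sf
        elif alternative == "less":
            p = cdf
        else:
            p = min(1.0, 2.0 * min(cdf, sf))
        return TestResult(u, p, "exact", n1, n2)

    n = n1 + n2
    mu = n1 * n2 / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return TestResult(u, 1.0, "approximate", n1, n2)
    sd = np.sqrt(var)
    if alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = 1.0 - ndtr(z)
    elif alternative == "less":
        z = (u - mu + 0.5) / sd
        p = float(ndtr(z))
    else:
        z = (abs(u - mu) - 0.5) / sd
        z = max(z, 0.0)
        p = 2.0 * (1.0 - ndtr(z))
    return TestResult(u, float(min(1.0, p)), "approximate", n1, n2)


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    P value from the t-distribution approximation with n-2 degrees of
    freedom.  A constant input yields an ``undefined`` flagged result
    (rho = nan) rather than a number.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("spearman requires at least 3 observations")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return CorrelationResult(float("nan"), float("nan"), n, undefined=True)
    rx = rankdata(x)
    ry = rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    rho = float((rx * ry).sum() / denom)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return CorrelationResult(rho, 0.0, n)
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p = float(2.0 * t_dist.sf(abs(t), n - 2))
    return CorrelationResult(rho, min(1.0, p), n)


def _log_hyper_prob(a: int, r1: int, r2: int, c1: int, n: int) -> float:
    # P(table | margins) for top-left cell a, row sums r1/r2, col sum c1
    return (
        gammaln(r1 + 1)
        + gammaln(r2 + 1)
        + gammaln(c1 + 1)
        + gammaln(n - c1 + 1)
        - gammaln(n + 1)
        - gammaln(a + 1)
        - gammaln(r1 - a + 1)
        - gammaln(c1 - a + 1)
        - gammaln(r2 - c1 + a + 1)
    )


def fisher_exact_2x2(table) -> TestResult:
    """Fisher's exact test for a 2x2 table.

    Two-sided P: sum of hypergeometric probabilities, over all tables with
    the observed margins, that do not exceed the observed table's
    probability (with a small relative tolerance, as in R's fisher.test).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("fisher_exact_2x2 expects a 2x2 table")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        tf = np.asarray(table, dtype=float)
        if np.any(tf < 0) or np.any(tf != np.round(tf)):
            raise ValueError("counts must be non-negative integers")
        t = tf.astype(int)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    if n == 0:
        return TestResult(float("nan"), 1.0, "exact", r1, r2)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    logp = np.array([_log_hyper_prob(k, r1, r2, c1, n) for k in range(lo, hi + 1)])
    p_obs = logp[a - lo]
    mask = logp <= p_obs + 1e-7
    p = float(np.exp(logp[mask]).sum())
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return TestResult(odds, min(1.0, p), "exact", r1, r2)


def roc_auc(scores, labels) -> float:
    """Area under the ROC curve by rank statistics.

    Equals (concordant pairs + half the tied pairs) / (n1*n0), i.e. the
    Mann-Whitney U of positive-class scores divided by n1*n0.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def pr_auc(scores, labels) -> float:
    """Area under the precision-recall curve in average-precision form.

    AP = sum over thresholds (taken at each distinct score, descending) of
    precision at the threshold times the increase in recall.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("pr_auc requires the positive class present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    lab = labels[order]
    tp = np.cumsum(lab)
    fp = np.cumsum(1 - lab)
    # thresholds at the last index of each distinct score
    last = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[last], fp[last]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def threshold_metrics(prob, labels, threshold: float = 0.5) -> ThresholdMetrics:
    """Accuracy, precision, recall and F1 at a probability cutoff.

    Precision is reported as 0 (and flagged) when nothing is predicted
    positive.
    """
    prob = np.asarray(prob, dtype=float)
    labels = np.asarray(labels).astype(int)
    pred = (prob >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    n = tp + fp + fn + tn
    acc = (tp + tn) / n if n else float("nan")
    no_pos = (tp + fp) == 0
    prec = 0.0 if no_pos else tp / (tp + fp)
    rec = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 0.0 if (prec + rec) == 0 else 2 * prec * rec / (prec + rec)
    return ThresholdMetrics(acc, prec, rec, f1, no_positive_predictions=no_pos)


@dataclass(frozen=True)
class OLSResult:
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int
    resid: np.ndarray = field(repr=False)
    names: tuple = ()

    def summary_frame(self):
        import pandas as pd

        names = self.names or [f"x{i}" for i in range(len(self.params))]
        return pd.DataFrame(
            {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues},
            index=list(names),
        )


def ols_fit(y, X, names=None) -> OLSResult:
    """Ordinary least squares with per-coefficient t tests.

    The caller supplies the full design matrix (including the intercept
    column).  Rank deficiency raises :class:`CollinearityError` naming the
    dependent columns (identified from the QR decomposition's R diagonal).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more rows ({n}) than columns ({k})")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = max(n, k) * np.finfo(float).eps * (diag.max() if diag.size else 1.0)
    dependent = np.where(diag <= tol)[0]
    if dependent.size:
        cols = [names[i] for i in dependent] if names else dependent
        raise CollinearityError(cols)
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    df = n - k
    sigma2 = float(resid @ resid) / df
    xtx_inv = np.linalg.inv(r.T @ r)
    bse = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(bse > 0, beta / bse, np.inf * np.sign(beta))
    pvals = 2.0 * t_dist.sf(np.abs(tvals), df)
    return OLSResult(beta, bse, tvals, np.minimum(pvals, 1.0), df, resid, tuple(names or ()))


def benjamini_hochberg(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (opt-in; raw P is the default
    everywhere in this package)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
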