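"""Unit and property tests for the statistical primitives, each checked
against an independent oracle (enumeration, scipy, sklearn, pseudo-inverse)."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as ss
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from pwabs import stats


def mwu_brute_force(x, y):
    """Exact two-sided Mann-Whitney P by enumerating all label assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    n = len(pooled)

    def u_of(idx):
        xs = pooled[list(idx)]
        ys = pooled[[i for i in range(n) if i not in idx]]
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_of(tuple(range(n1)))
    us = [u_of(c) for c in itertools.combinations(range(n), n1)]
    le = sum(u <= u_obs + 1e-9 for u in us) / len(us)
    ge = sum(u >= u_obs - 1e-9 for u in us) / len(us)
    return u_obs, min(1.0, 2 * min(le, ge))


class TestMannWhitney:
    def test_disjoint_groups(self):
        res = stats.mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_identical_multisets_no_evidence(self):
        res = stats.mann_whitney_u([1, 1, 2, 2], [1, 1, 2, 2])
        assert res.p_value >= 0.99

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 7), (8, 9), (3, 8)])
    def test_exact_matches_enumeration(self, n1, n2, rng):
        x = rng.normal(size=n1)
        y = rng.normal(size=n2)
        res = stats.mann_whitney_u(x, y)
        assert res.method == "exact"
        u, p = mwu_brute_force(x, y)
        assert res.statistic == pytest.approx(u)
        assert res.p_value == pytest.approx(p)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_matches_scipy(self, alternative, rng):
        x = rng.normal(size=6)
        y = rng.normal(size=9) + 0.5
        res = stats.mann_whitney_u(x, y, alternative)
        ref = ss.mannwhitneyu(x, y, alternative=alternative, method="exact")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_tied_data_uses_corrected_approximation(self, rng):
        x = rng.integers(0, 4, size=12).astype(float)
        y = rng.integers(0, 4, size=15).astype(float)
        res = stats.mann_whitney_u(x, y)
        assert res.method == "approximate"
        ref = ss.mannwhitneyu(x, y, method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_swap_symmetry(self, rng):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        assert stats.mann_whitney_u(x, y).p_value == pytest.approx(
            stats.mann_whitney_u(y, x).p_value
        )

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            stats.mann_whitney_u([], [1.0])


class TestSpearman:
    @pytest.mark.parametrize(
        "x,y,expected",
        [((1, 2, 3, 4), (1, 2, 3, 4), 1.0),
         ((1, 2, 3), (3, 2, 1), -1.0),
         ((1, 2, 3, 4), (2, 1, 4, 3), 0.6)],
    )
    def test_known_rho(self, x, y, expected):
        assert stats.spearman(x, y).rho == pytest.approx(expected)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, size=20).astype(float)
        y = x + rng.normal(size=20)
        res = stats.spearman(x, y)
        ref = ss.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_flagged(self):
        res = stats.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert res.undefined
        assert math.isnan(res.rho)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=15, unique=True),
           st.integers(0, 2**31 - 1))
    def test_monotone_transform_invariance(self, x, seed):
        x = np.asarray(x, dtype=float)
        y = np.random.default_rng(seed).normal(size=len(x))
        base = stats.spearman(x, y).rho
        # exp(x/100) is strictly monotone and keeps distinct values distinct here
        assert stats.spearman(np.exp(x / 100), y).rho == pytest.approx(base)
        assert stats.spearman(x, 3 * y + 7).rho == pytest.approx(base)


def fisher_brute_force(a, b, c, d):
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    total = math.comb(n, c1)

    def prob(k):
        return math.comb(r1, k) * math.comb(r2, c1 - k) / total

    p_obs = prob(a)
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-9))


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [([[3, 1], [1, 3]], 34 / 70),
         ([[5, 0], [0, 5]], 2 / 252),
         ([[2, 2], [2, 2]], 1.0)],
    )
    def test_known_tables(self, table, expected):
        assert stats.fisher_exact_2x2(table).p_value == pytest.approx(expected)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_enumeration_and_transpose(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        p = stats.fisher_exact_2x2(table).p_value
        assert p == pytest.approx(fisher_brute_force(a, b, c, d))
        assert p == pytest.approx(stats.fisher_exact_2x2(np.transpose(table)).p_value)

    def test_rejects_bad_counts(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[1, -2], [0, 3]])
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2([[1.5, 2], [0, 3]])


class TestRankMetrics:
    def test_roc_examples(self):
        s = [0.9, 0.8, 0.7, 0.6]
        assert stats.roc_auc(s, [1, 1, 0, 0]) == 1.0
        assert stats.roc_auc(s, [1, 0, 1, 0]) == 0.75
        assert stats.roc_auc([0.5] * 4, [1, 0, 1, 0]) == 0.5

    def test_roc_equals_u_statistic(self, rng):
        for _ in range(50):
            s = rng.normal(size=20)
            lab = rng.integers(0, 2, size=20)
            lab[:2] = [0, 1]
            u = stats.mann_whitney_u(s[lab == 1], s[lab == 0]).statistic
            assert stats.roc_auc(s, lab) == pytest.approx(u / ((lab == 1).sum() * (lab == 0).sum()))

    def test_roc_complement_property(self, rng):
        s = rng.permutation(20).astype(float)  # tie-free
        lab = rng.integers(0, 2, size=20)
        lab[:2] = [0, 1]
        assert stats.roc_auc(s, lab) + stats.roc_auc(-s, lab) == pytest.approx(1.0)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            stats.roc_auc([0.1, 0.2], [1, 1])

    def test_pr_examples(self):
        assert stats.pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert stats.pr_auc([0.4, 0.3, 0.2, 0.1], [0, 0, 0, 1]) == pytest.approx(0.25)

    def test_pr_matches_sklearn(self, rng):
        for _ in range(50):
            s = rng.normal(size=25)
            lab = rng.integers(0, 2, size=25)
            lab[0] = 1
            assert stats.pr_auc(s, lab) == pytest.approx(average_precision_score(lab, s))

    def test_random_scores_pr_near_prevalence(self, rng):
        # E[AP] under random ranking approaches the prevalence as n grows
        vals = []
        lab = np.array([1] * 50 + [0] * 150)
        for _ in range(200):
            vals.append(stats.pr_auc(rng.normal(size=200), lab))
        assert np.mean(vals) == pytest.approx(0.25, abs=0.05)

    def test_roc_matches_sklearn_many(self, rng):
        for _ in range(200):
            s = rng.normal(size=30)
            lab = rng.integers(0, 2, size=30)
            lab[:2] = [0, 1]
            assert stats.roc_auc(s, lab) == pytest.approx(roc_auc_score(lab, s))


class TestThresholdMetrics:
    def test_perfect(self):
        m = stats.threshold_metrics([0.9, 0.9, 0.1, 0.1], [1, 1, 0, 0])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (1, 1, 1, 1)

    def test_all_negative_predictions(self):
        m = stats.threshold_metrics([0.1, 0.2, 0.3], [1, 0, 0])
        assert m.recall == 0
        assert m.accuracy == pytest.approx(2 / 3)
        assert m.no_positive_predictions

    def test_mixed_confusion(self):
        m = stats.threshold_metrics([0.9, 0.6, 0.4, 0.1], [1, 0, 1, 0])
        assert (m.accuracy, m.precision, m.recall, m.f1) == (0.5, 0.5, 0.5, 0.5)


class TestOLS:
    def test_exact_line(self):
        x = np.arange(1.0, 6.0)
        X = np.c_[np.ones(5), x]
        res = stats.ols_fit(2 * x, X)
        assert res.params == pytest.approx([0.0, 2.0], abs=1e-10)
        assert np.allclose(res.resid, 0)

    def test_matches_pinv_oracle(self, rng):
        X = np.c_[np.ones(30), rng.normal(size=(30, 3))]
        y = rng.normal(size=30)
        res = stats.ols_fit(y, X)
        beta = np.linalg.pinv(X) @ y
        assert res.params == pytest.approx(beta)
        resid = y - X @ beta
        s2 = resid @ resid / (30 - 4)
        bse = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        assert res.bse == pytest.approx(bse)
        t = beta / bse
        assert res.pvalues == pytest.approx(2 * ss.t.sf(np.abs(t), 26))

    def test_duplicate_column_raises(self, rng):
        x = rng.normal(size=10)
        X = np.c_[np.ones(10), x, x]
        with pytest.raises(stats.CollinearityError):
            stats.ols_fit(rng.normal(size=10), X)


def test_benjamini_hochberg_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.uniform(size=40)
    assert stats.benjamini_hochberg(p) == pytest.approx(
        multipletests(p, method="fdr_bh")[1]
    )
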