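"""Clinical-trait association: starred Spearman matrices, MMSE subscale
profiles, sex-stratified summaries, and age/sex-adjusted regressions.

Correlations are pairwise-complete Spearman (binary traits are rank-coded,
which for a 0/1 variable is the rank-biserial form of the same statistic);
regressions are complete-case OLS.  Significance stars follow the usual
convention: * P < 0.05, ** P < 0.01, *** P < 0.001, all strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats
from .simulate import MMSE_SUBSCALES

__all__ = [
    "AssociationMatrix",
    "TraitAssociation",
    "stars",
    "trait_correlations",
    "subscale_profile",
    "adjusted_regression",
    "box_summary",
    "SEX_CODE",
]

#: sex coding used for regression designs (logged in regression output)
SEX_CODE = {"M": 0, "F": 1}

NOT_COMPUTABLE = "NC"


def stars(p: float) -> str:
    """Significance stars; strict thresholds, NaN maps to not-computable."""
    if p is None or np.isnan(p):
        return NOT_COMPUTABLE
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class AssociationMatrix:
    """rho / p / stars / n frames, autoantibodies as rows, traits as columns."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    @property
    def star(self) -> pd.DataFrame:
        return self.p.apply(lambda col: col.map(stars))

    def summary(self) -> pd.DataFrame:
        out = self.rho.round(2).astype(str) + self.star
        return out.where(~self.rho.isna(), NOT_COMPUTABLE)

    def to_csv(self, prefix) -> None:
        self.rho.to_csv(f"{prefix}_rho.csv", index_label="autoantibody")
        self.p.to_csv(f"{prefix}_p.csv", index_label="autoantibody")
        self.star.to_csv(f"{prefix}_stars.csv", index_label="autoantibody")


def _numeric_trait(subjects: pd.DataFrame, trait: str) -> pd.Series:
    s = subjects[trait]
    if s.dtype == object:
        uniq = set(s.dropna().unique())
        if uniq <= {"M", "F"}:
            return s.map(SEX_CODE).astype(float)
        return pd.to_numeric(s, errors="coerce")
    return s.astype(float)


def trait_correlations(au_subset: pd.DataFrame, subjects: pd.DataFrame,
                       traits, min_pairs: int = 3) -> AssociationMatrix:
    """Pairwise-complete Spearman for every (autoantibody, trait) cell.

    Cells with fewer than ``min_pairs`` complete pairs, or a constant vector,
    are marked not-computable (NaN rho/p).  ``subjects`` must be indexed by
    (or carry) subject_id matching ``au_subset``'s rows.
    """
    subj = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    subj = subj.reindex(au_subset.index)
    traits = list(traits)
    rho = pd.DataFrame(index=au_subset.columns, columns=traits, dtype=float)
    pvals = rho.copy()
    npairs = pd.DataFrame(0, index=au_subset.columns, columns=traits, dtype=int)
    for trait in traits:
        tv = _numeric_trait(subj, trait)
        for ab in au_subset.columns:
            pair = pd.concat([au_subset[ab], tv], axis=1).dropna()
            npairs.loc[ab, trait] = len(pair)
            if len(pair) < min_pairs:
                continue
            res = stats.spearman(pair.iloc[:, 0], pair.iloc[:, 1])
            if not res.undefined:
                rho.loc[ab, trait] = res.rho
                pvals.loc[ab, trait] = res.p_value
    return AssociationMatrix(rho, pvals, npairs)


def subscale_profile(ab: pd.Series, subjects: pd.DataFrame,
                     subscales=tuple(MMSE_SUBSCALES)) -> pd.DataFrame:
    """Spearman rho/p of one autoantibody against each MMSE subscale."""
    mat = trait_correlations(ab.to_frame(), subjects, list(subscales))
    out = pd.DataFrame({"rho": mat.rho.iloc[0], "p": mat.p.iloc[0], "n": mat.n.iloc[0]})
    out["star"] = out["p"].map(stars)
    return out


def adjusted_regression(trait: str, ab: pd.Series, subjects: pd.DataFrame):
    """Univariate (trait ~ ab) and multivariate (trait ~ age + sex + ab) OLS.

    Complete cases only; sex coded per ``SEX_CODE``.  Returns a dict with
    ``univariate`` and ``multivariate`` coefficient tables (coef, se, t, p).
    Too few complete cases for the degrees of freedom raises ValueError.
    """
    subj = subjects.set_index("subject_id") if "subject_id" in subjects.columns else subjects
    subj = subj.reindex(ab.index)
    df = pd.DataFrame({
        "trait": _numeric_trait(subj, trait),
        "ab": ab.astype(float),
        "age": subj["age"].astype(float),
        "sex": subj["sex"].map(SEX_CODE).astype(float),
    }).dropna()
    out = {"sex_coding": dict(SEX_CODE), "n": len(df)}
    for label, cols in (("univariate", ["ab"]), ("multivariate", ["age", "sex", "ab"])):
        k = len(cols) + 1
        if len(df) < k + 1:
            raise ValueError(
                f"{label}: need at least {k + 1} complete cases for {k} coefficients, "
                f"have {len(df)}"
            )
        X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy() for c in cols])
        res = stats.ols_fit(df["trait"].to_numpy(), X, names=["intercept", *cols])
        out[label] = res.summary_frame()
    return out


def box_summary(values, by) -> pd.DataFrame:
    """Box-plot statistics per group using the Tukey hinge convention:
    median, Q1/Q3 hinges, whiskers at the most extreme points within
    1.5 IQR of the hinges."""
    df = pd.DataFrame({"value": np.asarray(values, dtype=float), "group": np.asarray(by)})
    rows = {}
    for g, sub in df.groupby("group"):
        v = sub["value"].dropna()
        q1, med, q3 = v.quantile([0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows[g] = {"n": len(v), "median": med, "q1": q1, "q3": q3,
                   "whisker_low": lo, "whisker_high": hi}
    return pd.DataFrame(rows).T


class TraitAssociation:
    """Model object: selected autoantibodies against clinical traits.

    ``TraitAssociation(au_subset, subjects, traits).fit()`` returns an
    :class:`AssociationMatrix`; :meth:`regress` runs the adjusted
    regressions for one (trait, autoantibody) pair.
    """

    def __init__(self, au_subset: pd.DataFrame, subjects: pd.DataFrame, traits=None):
        self.au_subset = pd.DataFrame(au_subset)
        self.subjects = subjects
        if traits is None:
            skip = {"subject_id", "diagnosis"}
            traits = [c for c in subjects.columns if c not in skip]
        self.traits = list(traits)

    def fit(self, min_pairs: int = 3) -> AssociationMatrix:
        return trait_correlations(self.au_subset, self.subjects, self.traits, min_pairs)

    def regress(self, trait: str, antibody: str):
        return adjusted_regression(trait, self.au_subset[antibody], self.subjects)
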