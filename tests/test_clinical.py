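"""Clinical-trait association: starred correlation matrices, subscale
profiles, and age/sex-adjusted regressions with parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from pwabs.clinical import (
    TraitAssociation,
    adjusted_regression,
    box_summary,
    stars,
    subscale_profile,
    trait_correlations,
)
from pwabs.simulate import MMSE_SUBSCALES


def make_subjects(n, rng, **traits):
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "diagnosis": ["AD"] * n,
        "sex": rng.choice(["M", "F"], size=n),
        "age": rng.uniform(70, 90, size=n),
        **traits,
    })


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.05, ""), (0.049999, "*"), (0.01, "*"), (0.009999, "**"),
         (0.001, "**"), (0.0009999, "***"), (0.5, ""), (float("nan"), "NC")],
    )
    def test_boundaries_exact(self, p, expected):
        assert stars(p) == expected


class TestTraitCorrelations:
    def test_antibody_vs_itself(self, rng):
        n = 20
        ab = pd.DataFrame({"AB1": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
        subjects = make_subjects(n, rng, pseudo=ab["AB1"].to_numpy())
        mat = trait_correlations(ab, subjects, ["pseudo"])
        assert mat.rho.loc["AB1", "pseudo"] == pytest.approx(1.0)

    def test_planted_driver_negative_and_starred(self, default_au):
        au, _, subjects, truth = default_au
        (driver, coef), = truth.trait_drivers["MMSE"].items()
        mat = trait_correlations(au.values[[driver]], subjects, ["MMSE"])
        assert coef < 0
        assert mat.rho.loc[driver, "MMSE"] < 0
        assert mat.star.loc[driver, "MMSE"] != ""

    def test_all_missing_trait_not_computable(self, rng):
        n = 10
        ab = pd.DataFrame({"AB1": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
        subjects = make_subjects(n, rng, hollow=[np.nan] * n)
        mat = trait_correlations(ab, subjects, ["hollow"])
        assert np.isnan(mat.rho.loc["AB1", "hollow"])
        assert mat.star.loc["AB1", "hollow"] == "NC"
        assert mat.n.loc["AB1", "hollow"] == 0

    def test_pairwise_n_counts_complete_pairs(self, rng):
        n = 12
        trait = rng.normal(size=n)
        trait[:4] = np.nan
        ab = pd.DataFrame({"AB1": rng.normal(size=n)}, index=[f"s{i}" for i in range(n)])
        subjects = make_subjects(n, rng, sparse=trait)
        mat = trait_correlations(ab, subjects, ["sparse"])
        assert mat.n.loc["AB1", "sparse"] == 8

    def test_binary_trait_rank_coded(self, rng):
        n = 30
        flag = rng.integers(0, 2, size=n)
        ab = pd.DataFrame({"AB1": flag * 5 + rng.normal(size=n) * 0.1},
                          index=[f"s{i}" for i in range(n)])
        subjects = make_subjects(n, rng, flag=flag)
        mat = trait_correlations(ab, subjects, ["flag"])
        assert mat.rho.loc["AB1", "flag"] > 0.8


class TestSubscaleProfile:
    def test_recall_coupled_driver_peaks_at_recall(self, default_au):
        au, _, subjects, truth = default_au
        (driver, _), = truth.trait_drivers["Recall"].items()
        prof = subscale_profile(au.values[driver], subjects)
        assert list(prof.index) == list(MMSE_SUBSCALES)
        assert prof["rho"].abs().idxmax() in ("Recall", "Registration")
        assert prof.loc["Recall", "rho"] < 0

    def test_null_antibody_near_nominal_rejections(self, rng):
        """Uncoupled antibody: subscale correlations behave like a null."""
        n = 35
        rejections = []
        for rep in range(20):
            ab = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)],
                           name="AB")
            subs = {k: rng.normal(3, 1, size=n) for k in MMSE_SUBSCALES}
            subjects = make_subjects(n, rng, **subs)
            prof = subscale_profile(ab, subjects)
            rejections.extend((prof["p"] < 0.05).tolist())
        assert np.mean(rejections) < 0.12

    def test_constant_subscale_not_computable(self, rng):
        n = 10
        ab = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)], name="AB")
        subs = {k: np.full(n, 2.0) for k in MMSE_SUBSCALES}
        subjects = make_subjects(n, rng, **subs)
        prof = subscale_profile(ab, subjects)
        assert prof["star"].eq("NC").all()


class TestAdjustedRegression:
    def test_ab_effect_survives_adjustment(self, rng):
        n = 60
        ab = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        trait = 3.0 * ab.to_numpy() + rng.normal(0, 0.3, size=n)
        subjects = make_subjects(n, rng, score=trait)
        out = adjusted_regression("score", ab, subjects)
        multi = out["multivariate"]
        assert multi.loc["ab", "p"] < 0.001
        assert multi.loc["ab", "coef"] == pytest.approx(3.0, abs=0.3)
        assert multi.loc["sex", "p"] > 0.05

    def test_sex_confounding_removed(self, rng):
        """Trait driven purely by sex; antibody correlates with sex but not
        with the trait given sex: adjustment strips its significance."""
        n = 80
        sex = rng.integers(0, 2, size=n)
        ab = pd.Series(sex * 2.0 + rng.normal(0, 0.5, size=n),
                       index=[f"s{i}" for i in range(n)])
        trait = 5.0 * sex + rng.normal(0, 0.5, size=n)
        subjects = make_subjects(n, rng, score=trait)
        subjects["sex"] = np.where(sex == 1, "F", "M")
        out = adjusted_regression("score", ab, subjects)
        assert out["univariate"].loc["ab", "p"] < 0.001
        assert out["multivariate"].loc["ab", "p"] > 0.05

    def test_insufficient_cases_raise(self, rng):
        n = 4  # multivariate (age + sex + ab + intercept) needs >= 5 complete cases
        ab = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        subjects = make_subjects(n, rng, score=rng.normal(size=n))
        with pytest.raises(ValueError, match="complete cases"):
            adjusted_regression("score", ab, subjects)

    def test_noise_free_recovery(self, rng):
        n = 40
        ab = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        subjects = make_subjects(n, rng, score=2.5 * ab.to_numpy())
        out = adjusted_regression("score", ab, subjects)
        assert out["multivariate"].loc["ab", "coef"] == pytest.approx(2.5, abs=1e-8)


class TestSummaries:
    def test_box_summary_hinge_convention(self):
        vals = np.r_[np.arange(1.0, 13.0), 100.0]
        groups = ["g"] * 13
        row = box_summary(vals, groups).loc["g"]
        q1, q3 = np.percentile(vals, [25, 75])
        assert row["q1"] == pytest.approx(q1)
        assert row["q3"] == pytest.approx(q3)
        assert row["whisker_high"] == 12.0  # outlier at 100 excluded
        assert row["whisker_low"] == 1.0

    def test_trait_association_model_surface(self, default_au):
        au, _, subjects, truth = default_au
        sel = sorted(truth.elevated_union)[:4]
        mat = TraitAssociation(au.values[sel], subjects).fit()
        assert mat.rho.shape[0] == 4
        assert "MMSE" in mat.rho.columns
        summary = mat.summary()
        assert summary.shape == mat.rho.shape
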