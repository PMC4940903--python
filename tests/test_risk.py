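"""Logistic risk models: closed-form oracles, selection and interactions."""

import numpy as np
import pandas as pd
import pytest

from owratio.risk import (
    CohortLogit,
    backward_select,
    fit_univariate,
    screen_interactions,
    two_by_two_or,
)
from owratio.simulate import SimulationConfig, generate
from owratio.pipeline import classify_cohort
from owratio.cohort import attach_strata, derive_categories
from owratio.growth import standard_normal_reference


def _prepared_cohort(seed, **cfg_kwargs):
    cfg = SimulationConfig(seed=seed, **cfg_kwargs)
    gen = generate(cfg)
    df = classify_cohort(gen.cohort, standard_normal_reference())
    df = derive_categories(df)
    df = attach_strata(df, gen.parishes)
    df["overweight"] = df["overweight"].astype(bool)
    return df, gen.truth


class TestTwoByTwoOr:
    def test_symmetric_table_gives_unity(self):
        or_, _ = two_by_two_or(1, 1, 1, 1)
        assert or_ == pytest.approx(1.0)

    def test_lga_table_reconstruction(self):
        # 18 of 66 LGA children overweight; 224 of 1954 others
        or_, (lo, hi) = two_by_two_or(18, 48, 224, 1730)
        assert round(or_, 2) == 2.90
        assert lo == pytest.approx(1.66, abs=0.02)
        assert hi == pytest.approx(5.07, abs=0.02)

    def test_gender_table_reconstruction(self):
        or_, _ = two_by_two_or(134, 879, 108, 905)
        assert round(or_, 2) == 1.28

    def test_zero_cell_flagged_unstable(self):
        _, ci = two_by_two_or(0, 10, 5, 100)
        assert ci == (0.0, np.inf)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            two_by_two_or(-1, 1, 1, 1)


class TestUnivariate:
    def test_binary_predictor_matches_cross_product_oracle(self, study_classified):
        """The ML logistic OR on a binary predictor equals the 2x2 ratio."""
        df = study_classified.dropna(subset=["lga"])
        a = int(((df.lga == "yes") & df.overweight).sum())
        b = int(((df.lga == "yes") & ~df.overweight).sum())
        c = int(((df.lga == "no") & df.overweight).sum())
        d = int(((df.lga == "no") & ~df.overweight).sum())
        oracle, _ = two_by_two_or(a, b, c, d)
        fit = fit_univariate(study_classified, "lga")
        or_hat = fit.odds_ratios()["odds_ratio"].iloc[0]
        assert np.log(or_hat) == pytest.approx(np.log(oracle), abs=1e-6)

    def test_study_fixture_reproduces_published_univariate_ors(self, study_classified):
        expected = {
            "sex": [1.28],
            "lga": [2.90],
            "mother_smoking": [1.69],
            "mother_bmi_cat": [1.81, 2.19],
            "father_bmi_cat": [1.87, 4.26],
            "education": [2.03, 1.48],
        }
        for pred, ors in expected.items():
            fit = fit_univariate(study_classified, pred)
            got = fit.odds_ratios()["odds_ratio"].round(2).tolist()
            assert got == ors, pred

    def test_null_predictor_or_tends_to_one(self):
        rng = np.random.default_rng(3)
        n = 20_000
        df = pd.DataFrame(
            {
                "overweight": rng.uniform(size=n) < 0.12,
                "sex": rng.choice(["male", "female"], size=n),
            }
        )
        fit = fit_univariate(df, "sex")
        assert fit.odds_ratios()["odds_ratio"].iloc[0] == pytest.approx(1.0, abs=0.1)


class TestBackwardSelection:
    def test_single_strong_predictor_retained(self):
        df, _ = _prepared_cohort(11, missing_rates={})
        _, trace = backward_select(df, ["father_bmi_cat"])
        assert trace.final_terms == ["father_bmi_cat"]
        assert trace.steps == []

    def test_order_invariance_of_final_set(self, study_classified):
        cands = ["sex", "lga", "mother_smoking", "mother_bmi_cat", "father_bmi_cat", "education"]
        _, t1 = backward_select(study_classified, cands)
        _, t2 = backward_select(study_classified, list(reversed(cands)))
        assert set(t1.final_terms) == set(t2.final_terms)

    def test_null_retention_rate_near_exclusion_threshold(self):
        """Pure-noise candidates are retained at roughly the type-I rate."""
        rng = np.random.default_rng(5)
        n, reps = 4000, 40
        kept = 0
        total = 0
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "overweight": rng.uniform(size=n) < 0.12,
                    "sex": rng.choice(["male", "female"], size=n),
                    "mother_smoking": rng.choice(["no", "yes"], size=n, p=[0.9, 0.1]),
                }
            )
            _, trace = backward_select(df, ["sex", "mother_smoking"])
            kept += len(trace.final_terms)
            total += 2
        rate = kept / total
        # expect ~0.10 retention; allow generous Monte-Carlo slack
        assert 0.02 < rate < 0.25

    def test_all_predictors_removed_warns(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {
                "overweight": rng.uniform(size=3000) < 0.5,
                "sex": rng.choice(["male", "female"], size=3000),
            }
        )
        with pytest.warns(UserWarning, match="all predictors removed"):
            res, trace = backward_select(df, ["sex"])
        assert res is None and trace.final_terms == []

    def test_wald_criterion_agrees_on_study_fixture(self, study_classified):
        cands = ["sex", "lga", "mother_smoking", "mother_bmi_cat", "father_bmi_cat", "education"]
        _, t_wald = backward_select(study_classified, cands, criterion="wald")
        assert "mother_smoking" not in t_wald.final_terms


class TestInteractionScreen:
    def test_no_generated_interaction_leaves_fit_unchanged(self):
        df, _ = _prepared_cohort(21, missing_rates={})
        res = CohortLogit(df, ["sex", "father_bmi_cat"]).fit()
        out, tested = screen_interactions(res, df)
        assert out is res
        assert all(p >= 0.05 for _, p in tested)

    def test_strong_generated_interaction_detected(self):
        rng = np.random.default_rng(17)
        n = 6000
        sex = rng.choice(["male", "female"], size=n)
        smoke = rng.choice(["no", "yes"], size=n, p=[0.7, 0.3])
        lp = -2.2 + 1.8 * ((sex == "female") & (smoke == "yes"))
        df = pd.DataFrame(
            {
                "overweight": rng.uniform(size=n) < 1 / (1 + np.exp(-lp)),
                "sex": sex,
                "mother_smoking": smoke,
            }
        )
        res = CohortLogit(df, ["sex", "mother_smoking"]).fit()
        out, tested = screen_interactions(res, df)
        assert any(p < 0.05 for _, p in tested)
        assert any(":" in t for t in out.terms)

    def test_single_predictor_is_noop(self):
        df, _ = _prepared_cohort(23, missing_rates={})
        res = CohortLogit(df, ["sex"]).fit()
        out, tested = screen_interactions(res, df)
        assert out is res and tested == []


class TestCoverage:
    def test_wald_intervals_cover_generating_log_odds(self):
        """95 % Wald CIs cover the generating coefficients at nominal rate."""
        reps = 120
        hits = {"lga[yes]": 0, "father_bmi_cat[gt30]": 0}
        truth = {"lga[yes]": np.log(2.74), "father_bmi_cat[gt30]": np.log(3.49)}
        for r in range(reps):
            df, _ = _prepared_cohort(1000 + r, missing_rates={})
            fit = CohortLogit(
                df, ["sex", "lga", "mother_bmi_cat", "father_bmi_cat", "education"]
            ).fit()
            tab = fit.odds_ratios().set_index("term")
            for term in hits:
                lo = np.log(tab.loc[term, "ci_low"])
                hi = np.log(tab.loc[term, "ci_high"])
                hits[term] += int(lo <= truth[term] <= hi)
        for term, h in hits.items():
            assert 0.89 <= h / reps <= 0.99, (term, h / reps)
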