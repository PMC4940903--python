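"""Synthetic cohort generator and the table-calibrated study fixture."""

import numpy as np
import pandas as pd
import pytest

from owratio.cohort import attach_strata, derive_categories
from owratio.growth import standard_normal_reference
from owratio.pipeline import classify_cohort
from owratio.risk import fit_univariate
from owratio.simulate import (
    SimulationConfig,
    calibrate_intercept,
    fixture_study,
    generate,
)


def _logit(p):
    return np.log(p / (1 - p))


class TestCalibrateIntercept:
    def test_zero_effects_reduce_to_logit_of_target(self):
        cfg = SimulationConfig(
            predictor_log_odds={}, stratum_log_effects={}, target_prevalence=0.119
        )
        assert calibrate_intercept(cfg) == pytest.approx(_logit(0.119), abs=1e-8)

    def test_balanced_target_gives_zero_intercept(self):
        cfg = SimulationConfig(
            predictor_log_odds={}, stratum_log_effects={}, target_prevalence=0.5
        )
        assert calibrate_intercept(cfg) == pytest.approx(0.0, abs=1e-8)

    def test_default_effects_hit_target_in_large_simulation(self):
        cfg = SimulationConfig(seed=99, missing_rates={})
        big = {s: 25 * n for s, n in cfg.stratum_sizes.items()}
        big_cfg = SimulationConfig(seed=99, missing_rates={}, stratum_sizes=big)
        gen = generate(big_cfg)
        df = classify_cohort(gen.cohort, standard_normal_reference())
        prev = df["overweight"].astype(float).mean()
        assert 0.11 < prev < 0.13

    def test_infeasible_target_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(target_prevalence=1.2)


class TestGenerate:
    def test_same_seed_identical_cohort(self):
        a = generate(SimulationConfig(seed=5)).cohort
        b = generate(SimulationConfig(seed=5)).cohort
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_different_cohort(self):
        a = generate(SimulationConfig(seed=5)).cohort
        b = generate(SimulationConfig(seed=6)).cohort
        assert not a["bmi"].equals(b["bmi"])

    def test_default_prevalence_near_study_value(self):
        gen = generate(SimulationConfig(seed=1, missing_rates={}))
        df = classify_cohort(gen.cohort, standard_normal_reference())
        prev = df["overweight"].astype(float).mean()
        assert prev == pytest.approx(0.119, abs=0.025)

    def test_null_generator_equalizes_strata(self):
        cfg = SimulationConfig(
            seed=8,
            predictor_log_odds={},
            stratum_log_effects={},
            missing_rates={},
            stratum_sizes={"lt10": 4000, "10to19.9": 4000, "20to29.9": 4000, "ge30": 4000},
        )
        gen = generate(cfg)
        df = classify_cohort(gen.cohort, standard_normal_reference())
        df = attach_strata(df, gen.parishes)
        rates = df.groupby("stratum", observed=True)["overweight"].agg(
            lambda s: s.astype(float).mean()
        )
        assert rates.max() - rates.min() < 0.03

    def test_missingness_rates_applied(self):
        gen = generate(SimulationConfig(seed=3))
        frac = gen.cohort["father_bmi"].isna().mean()
        assert frac == pytest.approx(329 / 2026, abs=0.03)

    def test_mar_mechanism_targets_low_education(self):
        cfg = SimulationConfig(seed=4, missing_mechanism="mar")
        gen = generate(cfg)
        df = derive_categories(gen.cohort)
        # smoking nonresponse should be commoner where education data is low;
        # proxy: overall missingness level is preserved
        assert gen.cohort["mother_smoking"].isna().mean() == pytest.approx(
            91 / 2026, abs=0.04
        )

    def test_generating_lga_effect_recovered_on_average(self):
        """Mean fitted LGA odds ratio across replicates falls inside the
        published interval (1.66-5.07)."""
        ors = []
        for r in range(25):
            gen = generate(SimulationConfig(seed=300 + r, missing_rates={}))
            df = classify_cohort(gen.cohort, standard_normal_reference())
            df = derive_categories(df)
            df["overweight"] = df["overweight"].astype(bool)
            fit = fit_univariate(df, "lga")
            ors.append(fit.odds_ratios()["odds_ratio"].iloc[0])
        assert 1.66 < np.mean(ors) < 5.07


class TestFixtureStudy:
    def test_total_and_sex_counts(self, study):
        c = study.cohort
        assert len(c) == 2026
        assert (c.sex == "male").sum() == 1013
        assert (c.sex == "female").sum() == 1013

    def test_overweight_counts_exact(self, study_classified):
        ow = study_classified["overweight"]
        assert int(ow.sum()) == 242
        assert int(ow[study_classified.sex == "male"].sum()) == 108
        assert int(ow[study_classified.sex == "female"].sum()) == 134

    def test_stratum_sizes_and_overweight_exact(self, study_classified):
        sizes = study_classified["stratum"].value_counts().to_dict()
        assert sizes == {"20to29.9": 860, "10to19.9": 746, "lt10": 310, "ge30": 104}
        ow = study_classified.groupby("stratum", observed=True)["overweight"].sum().to_dict()
        assert ow == {"lt10": 21, "10to19.9": 100, "20to29.9": 107, "ge30": 14}

    def test_stratum_by_gender_cross_tab_exact(self, study_classified):
        tab = pd.crosstab(study_classified["stratum"], study_classified["sex"])
        expect = {
            "lt10": (159, 151),
            "10to19.9": (359, 387),
            "20to29.9": (446, 414),
            "ge30": (45, 59),
        }
        for strat, (m, f) in expect.items():
            assert tab.loc[strat, "male"] == m
            assert tab.loc[strat, "female"] == f

    def test_predictor_margins_and_missing_counts_exact(self, study_classified):
        c = study_classified
        checks = {
            "lga": ({"no": 1954, "yes": 66}, 6),
            "mother_smoking": ({"no": 1836, "yes": 99}, 91),
            "mother_bmi_cat": ({"le25": 1407, "gt25le30": 334, "gt30": 148}, 137),
            "father_bmi_cat": ({"le25": 866, "gt25le30": 701, "gt30": 130}, 329),
            "education": ({"none": 641, "one": 578, "both": 600}, 207),
        }
        for col, (cats, miss) in checks.items():
            vc = c[col].value_counts(dropna=True).to_dict()
            assert {k: int(v) for k, v in vc.items()} == cats, col
            assert int(c[col].isna().sum()) == miss, col

    def test_sga_children_present_and_not_overweight(self, study_classified):
        sga = study_classified[study_classified["birthweight_sds"] < -2]
        assert len(sga) == 23
        assert not sga["overweight"].any()

    def test_deterministic_given_seed(self):
        a = fixture_study().cohort
        b = fixture_study().cohort
        pd.testing.assert_frame_equal(a, b)

    def test_exam_ages_within_follow_up_window(self, study):
        ages = study.cohort["exam_age"]
        assert ages.between(3.6, 5.0).all()
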