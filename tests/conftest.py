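import pandas as pd
import pytest

from owratio import (
    attach_strata,
    classify_cohort,
    derive_categories,
    fixture_study,
    standard_normal_reference,
)


@pytest.fixture(scope="session")
def reference():
    return standard_normal_reference()


@pytest.fixture(scope="session")
def study():
    """The deterministic study-calibrated cohort (raw records + parishes)."""
    return fixture_study()


@pytest.fixture(scope="session")
def study_classified(study, reference):
    """Study cohort with outcome, LGA, categories and strata attached."""
    df = classify_cohort(study.cohort, reference)
    df = derive_categories(df)
    df = attach_strata(df, study.parishes)
    df = df[df["overweight"].notna()].copy()
    df["overweight"] = df["overweight"].astype(bool)
    return df
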