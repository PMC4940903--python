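"""Cohort data model: reading/validating input files, coding predictors into
analysis categories, and attaching neighbourhood purchasing-power strata.

The in-memory container is a pandas DataFrame with one row per child and a
fixed schema (:data:`COHORT_COLUMNS`).  Missing predictor values are explicit
(empty cell on disk, NaN/NA in memory) and are never dropped at read time;
complete-case filtering is a downstream, logged operation.

Neighbourhood strata group residential parishes by the proportion of resident
families with low household purchasing power: <10 %, 10-19.9 %, 20-29.9 %
and >=30 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "COHORT_COLUMNS",
    "STRATUM_LABELS",
    "ParishInfo",
    "read_cohort",
    "write_cohort",
    "read_parish_table",
    "categorize_bmi",
    "categorize_education",
    "assign_stratum",
    "attach_strata",
    "derive_categories",
    "completeness_report",
]

#: Required columns of a cohort file, in canonical order.
COHORT_COLUMNS = [
    "child_id",
    "sex",
    "exam_age",
    "bmi",
    "birthweight_sds",
    "mother_smoking",
    "mother_bmi",
    "father_bmi",
    "mother_postsecondary",
    "father_postsecondary",
    "parish_id",
]

#: Purchasing-power stratum labels, poorest-last, with interval convention
#: [0, 10), [10, 20), [20, 30), [30, 100] in percent of resident families
#: with low purchasing power.
STRATUM_LABELS = ["lt10", "10to19.9", "20to29.9", "ge30"]

_STRATUM_EDGES = (0.10, 0.20, 0.30)

BMI_CATEGORIES = ["le25", "gt25le30", "gt30"]
EDUCATION_CATEGORIES = ["none", "one", "both"]

_YESNO = {"yes": "yes", "no": "no", "1": "yes", "0": "no", "true": "yes", "false": "no"}


class SchemaError(ValueError):
    """Input file does not match the expected schema."""


@dataclass(frozen=True)
class ParishInfo:
    """A residential parish and its low-purchasing-power fraction."""

    parish_id: str
    low_pp_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_pp_fraction <= 1.0:
            raise ValueError(
                f"low_pp_fraction must lie in [0, 1], got {self.low_pp_fraction!r} "
                f"for parish {self.parish_id!r}"
            )


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

def _parse_yesno(series: pd.Series, column: str) -> pd.Series:
    out = series.astype("string").str.strip().str.lower().map(_YESNO)
    bad = series.notna() & out.isna() & (series.astype("string").str.strip() != "")
    if bad.any():
        # unparseable predictor cells become explicit missing values
        out[bad] = pd.NA
    return out


def read_cohort(path, sep: str | None = None) -> pd.DataFrame:
    """Read a cohort file (comma default, tab accepted) into the canonical frame.

    Unparseable cells in predictor columns become explicit missing values;
    the row count is preserved.  A malformed header or duplicated child ids
    raise :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep=sep, engine="python", dtype="string")
    missing_cols = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"cohort file lacks required columns: {missing_cols}")
    if df["child_id"].duplicated().any():
        dup = df.loc[df["child_id"].duplicated(), "child_id"].iloc[0]
        raise SchemaError(f"duplicate child_id {dup!r}")

    out = pd.DataFrame(index=df.index)
    out["child_id"] = df["child_id"].astype(str)
    sex = df["sex"].str.strip().str.lower()
    bad_sex = ~sex.isin(["male", "female"])
    if bad_sex.any():
        raise SchemaError(f"unknown sex code {sex[bad_sex].iloc[0]!r}")
    out["sex"] = sex
    for col in ("exam_age", "bmi", "birthweight_sds", "mother_bmi", "father_bmi"):
        out[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("mother_smoking", "mother_postsecondary", "father_postsecondary"):
        out[col] = _parse_yesno(df[col], col)
    pid = df["parish_id"].astype("string").str.strip()
    out["parish_id"] = pid.where(pid.notna() & (pid != ""), pd.NA)

    bad_bmi = out["bmi"].notna() & (out["bmi"] <= 0)
    if bad_bmi.any():
        raise SchemaError(f"non-positive bmi for child {out.loc[bad_bmi, 'child_id'].iloc[0]}")
    return out


def write_cohort(df: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a cohort frame; missing values become empty cells."""
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.loc[:, cols].to_csv(path, sep=sep, index=False, na_rep="")


def read_parish_table(path, sep: str | None = None) -> pd.DataFrame:
    """Read a parish table with columns parish_id, low_pp_fraction.

    Values may be fractions in [0, 1] or percentages in (1, 100]; the unit is
    auto-detected from the magnitude (a warning is emitted for percentages).
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    for col in ("parish_id", "low_pp_fraction"):
        if col not in df.columns:
            raise SchemaError(f"parish table lacks column {col!r}")
    frac = pd.to_numeric(df["low_pp_fraction"], errors="raise").astype(float)
    if (frac > 1.0).any():
        import warnings

        warnings.warn(
            "low_pp_fraction has values > 1; interpreting the column as percentages",
            stacklevel=2,
        )
        frac = frac / 100.0
    if ((frac < 0) | (frac > 1)).any():
        raise SchemaError("low_pp_fraction outside [0, 1] after unit detection")
    return pd.DataFrame(
        {"parish_id": df["parish_id"].astype(str), "low_pp_fraction": frac}
    )


# ---------------------------------------------------------------------------
# predictor coding
# ---------------------------------------------------------------------------

def categorize_bmi(bmi):
    """Code parental BMI into <=25, >25-30, >30 (both boundaries resolve down).

    Accepts scalars or arrays; missing stays missing; non-positive values
    raise.
    """
    arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    if np.any(arr[~np.isnan(arr)] <= 0):
        raise ValueError("non-positive BMI cannot be categorized")
    out = pd.Series(pd.NA, index=range(len(arr)), dtype="string")
    out[arr <= 25] = "le25"
    out[(arr > 25) & (arr <= 30)] = "gt25le30"
    out[arr > 30] = "gt30"
    cat = pd.Categorical(out, categories=BMI_CATEGORIES)
    if np.isscalar(bmi):
        return None if pd.isna(cat[0]) else str(cat[0])
    return pd.Series(cat)


def categorize_education(mother_postsecondary, father_postsecondary):
    """Parental educational level: none / one / both post-secondary.

    Derived from the two parent-level yes/no fields; a missing parent makes
    the category missing (conservative propagation).
    """
    scalar_in = (mother_postsecondary is None or isinstance(mother_postsecondary, str)) and (
        father_postsecondary is None or isinstance(father_postsecondary, str)
    )
    if scalar_in:
        mother_postsecondary = [mother_postsecondary]
        father_postsecondary = [father_postsecondary]
    m = pd.Series(mother_postsecondary, dtype="string")
    f = pd.Series(father_postsecondary, dtype="string")
    n_yes = ((m == "yes").fillna(False).astype(int)
             + (f == "yes").fillna(False).astype(int)).to_numpy()
    out = pd.Series(pd.Categorical(
        np.array(EDUCATION_CATEGORIES, dtype=object)[n_yes],
        categories=EDUCATION_CATEGORIES,
    ))
    out[m.isna() | f.isna()] = pd.NA
    if scalar_in:
        return None if pd.isna(out.iloc[0]) else str(out.iloc[0])
    return out


def assign_stratum(parish: ParishInfo) -> str:
    """Map a parish to its purchasing-power stratum label."""
    f = parish.low_pp_fraction
    for label, edge in zip(STRATUM_LABELS, _STRATUM_EDGES):
        if f < edge:
            return label
    return STRATUM_LABELS[-1]


def attach_strata(cohort: pd.DataFrame, parishes: pd.DataFrame) -> pd.DataFrame:
    """Attach a ``stratum`` column by joining the parish table.

    Children without a parish (not geo-codable) get a missing stratum and are
    excluded from neighbourhood analyses downstream, but retained here.
    """
    lookup = {
        row.parish_id: assign_stratum(ParishInfo(row.parish_id, row.low_pp_fraction))
        for row in parishes.itertuples()
    }
    known = cohort["parish_id"].dropna().unique()
    unknown = [p for p in known if p not in lookup]
    if unknown:
        raise SchemaError(f"parish ids missing from parish table: {unknown[:5]}")
    out = cohort.copy()
    out["stratum"] = pd.Categorical(
        [lookup.get(p) if not pd.isna(p) else None for p in cohort["parish_id"]],
        categories=STRATUM_LABELS,
    )
    return out


def derive_categories(cohort: pd.DataFrame) -> pd.DataFrame:
    """Add analysis categories: mother_bmi_cat, father_bmi_cat, education.

    If the input already carries a pre-coded ``education`` column it is kept.
    """
    out = cohort.copy()
    out["mother_bmi_cat"] = categorize_bmi(out["mother_bmi"].to_numpy(dtype=float)).values
    out["father_bmi_cat"] = categorize_bmi(out["father_bmi"].to_numpy(dtype=float)).values
    if "education" not in out.columns:
        out["education"] = categorize_education(
            out["mother_postsecondary"], out["father_postsecondary"]
        ).values
    return out


def completeness_report(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-predictor category counts and missing counts (a validation report)."""
    df = derive_categories(cohort)
    rows = []
    specs = [
        ("sex", ["male", "female"]),
        ("mother_smoking", ["no", "yes"]),
        ("mother_bmi_cat", BMI_CATEGORIES),
        ("father_bmi_cat", BMI_CATEGORIES),
        ("education", EDUCATION_CATEGORIES),
    ]
    if "lga" in df.columns:
        specs.insert(1, ("lga", ["no", "yes"]))
    for col, cats in specs:
        counts = df[col].value_counts(dropna=True)
        for cat in cats:
            rows.append({"predictor": col, "category": cat, "n": int(counts.get(cat, 0))})
        rows.append({"predictor": col, "category": "<missing>", "n": int(df[col].isna().sum())})
    return pd.DataFrame(rows)
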