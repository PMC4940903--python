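"""BMI standard-deviation scores against a growth reference, and overweight / LGA
classification.

A growth reference is an age x sex grid of BMI means and SDs.  The standard
deviation score (SDS, a z-score) of an observed BMI at a given age and sex is

    sds = (bmi - mean(age, sex)) / sd(age, sex)

with the mean and SD linearly interpolated on the reference age grid.  A child
is classified overweight when the SDS strictly exceeds a sex-specific cutoff
(defaults 1.19 for boys, 1.11 for girls, the SDS expression of the IOTF
age-4 overweight thresholds); large for gestational age (LGA) when the
birthweight SDS strictly exceeds 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GrowthReference",
    "SdsCutoffs",
    "compute_sds",
    "classify_overweight",
    "classify_lga",
    "standard_normal_reference",
]

SEXES = ("male", "female")


class GrowthReferenceError(ValueError):
    """Invalid growth-reference table or out-of-range evaluation."""


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValueError(f"unknown sex code {sex!r}; expected one of {SEXES}")
    return sex


@dataclass(frozen=True)
class SdsCutoffs:
    """SDS thresholds for overweight (sex-specific) and LGA classification.

    All comparisons are strict (``>``): a score exactly at the cutoff is not
    classified as overweight / LGA.
    """

    boys_cutoff: float = 1.19
    girls_cutoff: float = 1.11
    lga_cutoff: float = 2.0

    def __post_init__(self) -> None:
        for name in ("boys_cutoff", "girls_cutoff", "lga_cutoff"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")

    def overweight_cutoff(self, sex: str) -> float:
        return self.boys_cutoff if _check_sex(sex) == "male" else self.girls_cutoff


@dataclass
class GrowthReference:
    """Age x sex grid of BMI mean and SD supporting SDS computation.

    Parameters
    ----------
    age_grid : mapping sex -> strictly increasing array of ages (years)
    mean_bmi : mapping sex -> BMI means (kg/m^2) on the grid
    sd_bmi : mapping sex -> BMI SDs (kg/m^2, all > 0) on the grid
    """

    age_grid: dict = field(default_factory=dict)
    mean_bmi: dict = field(default_factory=dict)
    sd_bmi: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sex in self.age_grid:
            _check_sex(sex)
            ages = np.asarray(self.age_grid[sex], dtype=float)
            mean = np.asarray(self.mean_bmi[sex], dtype=float)
            sd = np.asarray(self.sd_bmi[sex], dtype=float)
            if ages.ndim != 1 or len(ages) < 2:
                raise GrowthReferenceError(f"{sex}: age grid needs >= 2 points")
            if np.any(np.diff(ages) <= 0):
                raise GrowthReferenceError(f"{sex}: age grid must be strictly increasing")
            if mean.shape != ages.shape or sd.shape != ages.shape:
                raise GrowthReferenceError(f"{sex}: grid arrays have mismatched lengths")
            if np.any(sd <= 0):
                raise GrowthReferenceError(f"{sex}: sd_bmi must be positive everywhere")
            self.age_grid[sex] = ages
            self.mean_bmi[sex] = mean
            self.sd_bmi[sex] = sd

    # -- construction -----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GrowthReference":
        """Build from a table with columns sex, age_years, mean_bmi, sd_bmi."""
        required = {"sex", "age_years", "mean_bmi", "sd_bmi"}
        missing = required - set(frame.columns)
        if missing:
            raise GrowthReferenceError(
                f"growth reference table lacks columns: {sorted(missing)}"
            )
        ref = cls()
        for sex, grp in frame.groupby("sex"):
            _check_sex(str(sex))
            grp = grp.sort_values("age_years")
            ref.age_grid[sex] = np.asarray(grp["age_years"], dtype=float)
            ref.mean_bmi[sex] = np.asarray(grp["mean_bmi"], dtype=float)
            ref.sd_bmi[sex] = np.asarray(grp["sd_bmi"], dtype=float)
        ref.__post_init__()
        return ref

    @classmethod
    def from_file(cls, path, sep: str = ",") -> "GrowthReference":
        return cls.from_frame(pd.read_csv(path, sep=sep))

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for sex in self.age_grid:
            parts.append(
                pd.DataFrame(
                    {
                        "sex": sex,
                        "age_years": self.age_grid[sex],
                        "mean_bmi": self.mean_bmi[sex],
                        "sd_bmi": self.sd_bmi[sex],
                    }
                )
            )
        return pd.concat(parts, ignore_index=True)

    # -- evaluation -------------------------------------------------------
    def _interp(self, table: dict, age, sex: str) -> np.ndarray:
        _check_sex(sex)
        if sex not in self.age_grid:
            raise GrowthReferenceError(f"reference has no grid for sex {sex!r}")
        ages = np.atleast_1d(np.asarray(age, dtype=float))
        grid = self.age_grid[sex]
        out_of_range = (ages < grid[0]) | (ages > grid[-1])
        if np.any(out_of_range):
            bad = ages[out_of_range][0]
            raise GrowthReferenceError(
                f"age {bad:g} outside reference coverage [{grid[0]:g}, {grid[-1]:g}]"
            )
        return np.interp(ages, grid, table[sex])

    def mean(self, age, sex: str):
        out = self._interp(self.mean_bmi, age, sex)
        return float(out[0]) if np.isscalar(age) else out

    def sd(self, age, sex: str):
        out = self._interp(self.sd_bmi, age, sex)
        return float(out[0]) if np.isscalar(age) else out


def compute_sds(bmi, age, sex: str, reference: GrowthReference):
    """Sex- and age-specific BMI standard deviation score.

    Accepts scalars or arrays for ``bmi`` and ``age`` (broadcast together).
    Raises if any age lies outside the reference grid or any BMI is
    non-positive.
    """
    bmi_arr = np.atleast_1d(np.asarray(bmi, dtype=float))
    ok = np.isnan(bmi_arr) | (bmi_arr > 0)
    if not np.all(ok):
        raise ValueError(f"non-positive bmi {bmi_arr[~ok][0]:g}")
    mean = reference._interp(reference.mean_bmi, age, sex)
    sd = reference._interp(reference.sd_bmi, age, sex)
    sds = (bmi_arr - mean) / sd
    return float(sds[0]) if np.isscalar(bmi) and np.isscalar(age) else sds


def classify_overweight(sds, sex: str, cutoffs: SdsCutoffs | None = None):
    """Overweight iff sds strictly exceeds the sex-specific cutoff.

    NaN scores propagate to a missing (pandas NA) classification.
    """
    cutoffs = cutoffs or SdsCutoffs()
    cut = cutoffs.overweight_cutoff(sex)
    arr = np.atleast_1d(np.asarray(sds, dtype=float))
    out = pd.array(arr > cut, dtype="boolean")
    out[np.isnan(arr)] = pd.NA
    return bool(out[0]) if np.isscalar(sds) and not pd.isna(out[0]) else (
        out[0] if np.isscalar(sds) else out
    )


def classify_lga(birthweight_sds, cutoffs: SdsCutoffs | None = None):
    """LGA iff birthweight SDS strictly exceeds the cutoff (default 2 SDS).

    SGA children (large negative scores) fall in the non-LGA class; missing
    scores yield a missing classification.
    """
    cutoffs = cutoffs or SdsCutoffs()
    arr = np.atleast_1d(np.asarray(birthweight_sds, dtype=float))
    out = pd.array(arr > cutoffs.lga_cutoff, dtype="boolean")
    out[np.isnan(arr)] = pd.NA
    scalar = np.isscalar(birthweight_sds)
    if scalar:
        return out[0] if pd.isna(out[0]) else bool(out[0])
    return out


def standard_normal_reference(
    age_min: float = 3.0,
    age_max: float = 6.0,
    mean_start: float = 16.8,
    mean_end: float = 15.8,
    sd: float = 1.4,
    n_points: int = 13,
) -> GrowthReference:
    """Synthetic reference under which SDS is exactly standard normal when BMI
    is drawn as mean(age) + Z * sd with Z ~ N(0, 1).

    Shipped for testing and for the synthetic cohort; it is not a national
    growth reference.  The default mean declines gently with age, mimicking
    the adiposity dip of early childhood.
    """
    ref = GrowthReference()
    ages = np.linspace(age_min, age_max, n_points)
    means = np.interp(ages, [age_min, age_max], [mean_start, mean_end])
    for sex in SEXES:
        ref.age_grid[sex] = ages.copy()
        ref.mean_bmi[sex] = means.copy()
        ref.sd_bmi[sex] = np.full_like(ages, sd)
    ref.__post_init__()
    return ref
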