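"""Indirect standardization of overweight counts across neighbourhood strata.

For each stratum *i* the observed overweight count ``O_i`` is compared with the
expected count ``E_i`` obtained by applying cohort-wide overweight rates —
computed per cell of a cross-classification of adjustment predictors — to the
stratum's composition:

    E_i = sum_cells  n_{i,cell} * rate_cell

The ratio O_i / E_i is the crude (COR) or adjusted (AOR) overweight ratio,
depending on the adjustment set, with an exact Poisson confidence interval for
O_i (chi-square quantile form) divided by E_i.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import STRATUM_LABELS

__all__ = [
    "StratumCounts",
    "RatioEstimate",
    "poisson_exact_ci",
    "ratio_with_ci",
    "expected_counts",
    "IndirectStandardization",
    "cor_table",
    "aor_table",
]

#: Default adjustment set of the crude ratios.  The crude analysis keeps a
#: gender standardization (expected counts built from sex-specific rates);
#: pass ``adjust_vars=[]`` for a fully crude single-rate analysis.
CRUDE_ADJUST = ["sex"]

#: Adjustment set of the adjusted ratios: the predictors retained by backward
#: selection of the risk model.
FULL_ADJUST = ["sex", "lga", "mother_bmi_cat", "father_bmi_cat", "education"]


@dataclass(frozen=True)
class StratumCounts:
    """Observed and expected overweight counts in one neighbourhood stratum."""

    stratum: str
    observed: int
    expected: float
    n: int

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0 or self.n < 0:
            raise ValueError("counts must be non-negative")
        if self.observed > self.n:
            raise ValueError(
                f"stratum {self.stratum}: observed {self.observed} exceeds n {self.n}"
            )


@dataclass(frozen=True)
class RatioEstimate:
    """An O/E ratio with its exact confidence interval."""

    stratum: str
    observed: int
    expected: float
    ratio: float
    ci95: tuple
    kind: str = "crude"

    def __str__(self) -> str:
        lo, hi = self.ci95
        return f"{self.stratum}: {self.ratio:.2f} ({lo:.2f}-{hi:.2f})"


def poisson_exact_ci(observed: int, level: float = 0.95) -> tuple:
    """Exact (Garwood) confidence limits for a Poisson mean given one count.

    Lower limit is 0 when the count is 0.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    alpha = 1.0 - level
    lo = 0.0 if observed == 0 else stats.chi2.ppf(alpha / 2, 2 * observed) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * (observed + 1)) / 2.0
    return float(lo), float(hi)


def ratio_with_ci(counts: StratumCounts, level: float = 0.95, kind: str = "crude") -> RatioEstimate:
    """O/E ratio with exact Poisson interval for O divided by E."""
    if counts.expected <= 0:
        raise ValueError(f"stratum {counts.stratum}: expected count must be positive")
    lo, hi = poisson_exact_ci(counts.observed, level)
    return RatioEstimate(
        stratum=counts.stratum,
        observed=counts.observed,
        expected=counts.expected,
        ratio=counts.observed / counts.expected,
        ci95=(lo / counts.expected, hi / counts.expected),
        kind=kind,
    )


def expected_counts(
    cohort: pd.DataFrame,
    adjust_vars: list | None = None,
    outcome: str = "overweight",
    stratum_col: str = "stratum",
    rate_cohort: pd.DataFrame | None = None,
) -> list:
    """Observed and indirectly standardized expected counts per stratum.

    Rates are computed per cell of the cross-classification of ``adjust_vars``
    on ``rate_cohort`` (default: the same records), then applied to each
    stratum's composition.  Records without a stratum contribute to the rates
    but not to any stratum's counts.  With an empty adjustment set the
    expected count is ``n_i`` times the overall rate.

    All records must be non-missing on the outcome and the adjustment
    variables (apply a complete-case filter first).
    """
    adjust_vars = list(adjust_vars) if adjust_vars is not None else []
    rates_df = cohort if rate_cohort is None else rate_cohort
    for df, what in ((cohort, "cohort"), (rates_df, "rate cohort")):
        if df[outcome].isna().any():
            raise ValueError(f"{what} has missing outcome values")
        for v in adjust_vars:
            if df[v].isna().any():
                raise ValueError(
                    f"{what} has missing values in adjustment variable {v!r}; "
                    "apply a complete-case filter first"
                )

    def cell_key(df):
        keys = list(zip(*(df[v].astype(str) for v in adjust_vars)))
        return pd.Series(keys, index=df.index, dtype=object)

    y_rate = rates_df[outcome].astype(float)
    if adjust_vars:
        cell_rate = y_rate.groupby(cell_key(rates_df)).mean()
    else:
        overall_rate = y_rate.mean()

    geo = cohort[cohort[stratum_col].notna()]
    out = []
    for label in STRATUM_LABELS:
        sub = geo[geo[stratum_col].astype(str) == label]
        if len(sub) == 0:
            import warnings

            warnings.warn(f"stratum {label} is empty", stacklevel=2)
            out.append(StratumCounts(label, 0, 0.0, 0))
            continue
        if adjust_vars:
            n_cells = cell_key(sub).value_counts()
            missing_cells = n_cells.index.difference(cell_rate.index)
            if len(missing_cells):
                raise ValueError(
                    f"stratum {label} contains adjustment cells absent from the "
                    f"rate population: {list(missing_cells[:3])}"
                )
            e = float((n_cells * cell_rate.reindex(n_cells.index)).sum())
        else:
            e = len(sub) * overall_rate
        o = int(sub[outcome].astype(float).sum())
        out.append(StratumCounts(label, o, e, len(sub)))
    return out


class IndirectStandardization:
    """Model object computing O/E overweight ratios per neighbourhood stratum.

    Parameters
    ----------
    cohort : DataFrame with outcome, stratum and adjustment columns.
    adjust_vars : predictors whose cross-classified rates define the expected
        counts (``[]`` for one overall rate; default gender only).
    rate_cohort : optional larger frame on which the rates are computed (e.g.
        all children with outcome data, while ratios are formed on the
        geo-coded subset).

    ``fit()`` applies a logged complete-case filter on the adjustment
    variables and returns an :class:`IndirectStandardizationResults`.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        adjust_vars: list | None = None,
        outcome: str = "overweight",
        stratum_col: str = "stratum",
        rate_cohort: pd.DataFrame | None = None,
        kind: str | None = None,
    ) -> None:
        self.cohort = cohort
        self.adjust_vars = CRUDE_ADJUST if adjust_vars is None else list(adjust_vars)
        self.outcome = outcome
        self.stratum_col = stratum_col
        self.rate_cohort = rate_cohort
        self.kind = kind or ("adjusted" if len(self.adjust_vars) > 1 else "crude")

    def fit(self, level: float = 0.95) -> "IndirectStandardizationResults":
        cols = [self.outcome] + self.adjust_vars
        cc = self.cohort.dropna(subset=cols)
        rates = self.rate_cohort
        if rates is not None:
            rates = rates.dropna(subset=cols)
        counts = expected_counts(
            cc, self.adjust_vars, self.outcome, self.stratum_col, rate_cohort=rates
        )
        ratios = [ratio_with_ci(c, level, kind=self.kind) for c in counts]
        return IndirectStandardizationResults(
            model=self, counts=counts, ratios=ratios,
            n_used=len(cc), n_dropped=len(self.cohort) - len(cc), level=level,
        )


class IndirectStandardizationResults:
    """Per-stratum observed/expected counts and O/E ratio estimates."""

    def __init__(self, model, counts, ratios, n_used, n_dropped, level):
        self.model = model
        self.counts = counts
        self.ratios = ratios
        self.n_used = n_used
        self.n_dropped = n_dropped
        self.level = level

    @property
    def pairs(self) -> list:
        """(O_i, E_i) pairs, the input of the empirical-Bayes stage."""
        return [(c.observed, c.expected) for c in self.counts]

    def summary(self) -> pd.DataFrame:
        rows = []
        for c, r in zip(self.counts, self.ratios):
            rows.append(
                {
                    "stratum": c.stratum,
                    "n": c.n,
                    "observed": c.observed,
                    "expected": round(c.expected, 1),
                    "ratio": round(r.ratio, 2),
                    "ci_low": round(r.ci95[0], 2),
                    "ci_high": round(r.ci95[1], 2),
                }
            )
        return pd.DataFrame(rows)

    def __str__(self) -> str:
        head = f"{self.model.kind} overweight ratios (n used = {self.n_used})"
        return head + "\n" + self.summary().to_string(index=False)


def cor_table(cohort: pd.DataFrame, adjust_vars: list | None = None, **kw) -> list:
    """Crude overweight ratios per stratum (default gender-standardized)."""
    adjust = CRUDE_ADJUST if adjust_vars is None else adjust_vars
    return IndirectStandardization(cohort, adjust, kind="crude", **kw).fit().ratios


def aor_table(cohort: pd.DataFrame, selected_predictors: list | None = None, **kw) -> list:
    """Adjusted overweight ratios per stratum, complete-case on the selected
    predictors (default: the backward-selection set)."""
    adjust = FULL_ADJUST if selected_predictors is None else list(selected_predictors)
    return IndirectStandardization(cohort, adjust, kind="adjusted", **kw).fit().ratios
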