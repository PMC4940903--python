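"""Logistic regression of overweight on child/parental predictors: univariate
odds ratios, multivariate fits with backward selection, and interaction
screening.

Predictors are categorical; each enters the model as dummy terms against a
reference category (the lowest-risk category of the study coding: male, not
LGA, non-smoking, BMI <=25, both parents post-secondary).  Predictor-level
exclusion tests are likelihood-ratio tests of all the predictor's dummy terms
jointly; Wald tests are available by configuration.

Maximum-likelihood fitting is delegated to statsmodels' Logit (Newton /
iteratively reweighted least squares).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "PREDICTOR_LEVELS",
    "two_by_two_or",
    "CohortLogit",
    "LogisticFitResults",
    "SelectionTrace",
    "fit_univariate",
    "backward_select",
    "screen_interactions",
]

#: Category order per predictor; the first level is the reference.
PREDICTOR_LEVELS = {
    "sex": ["male", "female"],
    "lga": ["no", "yes"],
    "mother_smoking": ["no", "yes"],
    "mother_bmi_cat": ["le25", "gt25le30", "gt30"],
    "father_bmi_cat": ["le25", "gt25le30", "gt30"],
    "education": ["both", "none", "one"],
}


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation for a named predictor."""


@dataclass
class SelectionTrace:
    """Ordered record of backward-selection steps."""

    steps: list = field(default_factory=list)  # (removed predictor, p-value)
    final_terms: list = field(default_factory=list)

    def removed(self) -> list:
        return [s[0] for s in self.steps]


def two_by_two_or(a: float, b: float, c: float, d: float, level: float = 0.95):
    """Odds ratio and Woolf (log-scale Wald) interval for a 2x2 table.

    ``a``/``b`` are exposed cases/non-cases, ``c``/``d`` unexposed.  With a
    zero cell the interval is flagged unstable (returned as (0, inf)); no
    continuity correction is applied.
    """
    for x in (a, b, c, d):
        if x < 0:
            raise ValueError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        or_ = np.inf if b * c == 0 and a * d > 0 else (a * d) / (b * c) if b * c else np.nan
        return or_, (0.0, np.inf)
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return or_, (or_ * np.exp(-z * se), or_ * np.exp(z * se))


def _design(df: pd.DataFrame, predictors: list, interactions: list | None = None):
    """Dummy-coded design matrix with intercept; returns (X, term labels,
    term -> predictor map)."""
    cols = {}
    terms = []
    owner = {}
    for pred in predictors:
        levels = PREDICTOR_LEVELS.get(pred)
        if levels is None:
            levels = sorted(df[pred].dropna().astype(str).unique())
        vals = df[pred].astype(str)
        observed = [l for l in levels if (vals == l).any()]
        if len(observed) < 2:
            raise ValueError(f"predictor {pred!r} has fewer than 2 observed categories")
        for lev in observed[1:]:
            name = f"{pred}[{lev}]"
            cols[name] = (vals == lev).astype(float).to_numpy()
            terms.append(name)
            owner[name] = pred
    for p1, p2 in interactions or []:
        for t1 in [t for t in terms if owner[t] == p1]:
            for t2 in [t for t in terms if owner[t] == p2]:
                prod = cols[t1] * cols[t2]
                if prod.sum() == 0:  # empty interaction cell: not estimable
                    continue
                name = f"{t1}:{t2}"
                cols[name] = prod
                terms.append(name)
                owner[name] = f"{p1}:{p2}"
    X = pd.DataFrame(cols, index=df.index)
    X.insert(0, "intercept", 1.0)
    return X, terms, owner


class CohortLogit:
    """Logistic model of a binary outcome on categorical cohort predictors.

    Complete-case on the outcome and the requested predictors.  ``fit()``
    returns a :class:`LogisticFitResults` with odds ratios, Wald intervals and
    per-predictor likelihood-ratio p-values.
    """

    def __init__(
        self,
        cohort: pd.DataFrame,
        predictors: list,
        outcome: str = "overweight",
        interactions: list | None = None,
    ) -> None:
        if not predictors:
            raise ValueError("need at least one predictor")
        self.cohort = cohort
        self.predictors = list(predictors)
        self.interactions = list(interactions or [])
        self.outcome = outcome
        cols = [outcome] + self.predictors
        self.data = cohort.dropna(subset=cols)

    def _fit_arrays(self, X: pd.DataFrame, y: np.ndarray, label: str):
        try:
            res = sm.Logit(y, X.to_numpy()).fit(disp=0, maxiter=200, tol=1e-10)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"logistic fit failed for {label}: {exc}") from exc
        if not res.mle_retvals.get("converged", True):
            raise SeparationError(
                f"logistic fit did not converge for {label} "
                "(possible complete separation)"
            )
        if np.any(np.abs(res.params) > 15):
            raise SeparationError(
                f"implausibly large coefficient for {label}: likely separation"
            )
        return res

    def fit(self) -> "LogisticFitResults":
        df = self.data
        y = df[self.outcome].astype(float).to_numpy()
        X, terms, owner = _design(df, self.predictors, self.interactions)
        res = self._fit_arrays(X, y, " + ".join(self.predictors))

        # per-predictor LR tests: refit without each predictor's terms
        lr_p = {}
        blocks = {}
        for t in terms:
            blocks.setdefault(owner[t], []).append(t)
        for pred, block in blocks.items():
            keep = [c for c in X.columns if c not in block]
            res0 = self._fit_arrays(X[keep], y, f"reduced model without {pred}")
            lr = 2.0 * (res.llf - res0.llf)
            lr_p[pred] = float(stats.chi2.sf(max(lr, 0.0), df=len(block)))
        return LogisticFitResults(
            model=self, sm_results=res, design_columns=list(X.columns),
            terms=terms, owner=owner, predictor_p=lr_p, n_used=len(df),
        )


class LogisticFitResults:
    """Odds ratios, intervals and tests from a fitted cohort logistic model."""

    def __init__(self, model, sm_results, design_columns, terms, owner, predictor_p, n_used):
        self.model = model
        self._res = sm_results
        self.design_columns = design_columns
        self.terms = terms
        self.owner = owner
        self.predictor_p = predictor_p  # LR p-value per predictor block
        self.n_used = n_used

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._res.params, index=self.design_columns)

    @property
    def llf(self) -> float:
        return float(self._res.llf)

    def odds_ratios(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        coefs = self.params
        ses = pd.Series(self._res.bse, index=self.design_columns)
        rows = []
        for t in self.terms:
            b, se = coefs[t], ses[t]
            rows.append(
                {
                    "term": t,
                    "predictor": self.owner[t],
                    "coef": b,
                    "odds_ratio": np.exp(b),
                    "ci_low": np.exp(b - z * se),
                    "ci_high": np.exp(b + z * se),
                    "wald_p": 2 * stats.norm.sf(abs(b / se)),
                }
            )
        return pd.DataFrame(rows)

    def wald_predictor_p(self) -> dict:
        """Joint Wald chi-square p-value per predictor block."""
        out = {}
        cov = np.asarray(self._res.cov_params())
        idx = {c: i for i, c in enumerate(self.design_columns)}
        blocks = {}
        for t in self.terms:
            blocks.setdefault(self.owner[t], []).append(idx[t])
        b = np.asarray(self._res.params)
        for pred, ii in blocks.items():
            bi = b[ii]
            vi = cov[np.ix_(ii, ii)]
            stat = float(bi @ np.linalg.solve(vi, bi))
            out[pred] = float(stats.chi2.sf(stat, df=len(ii)))
        return out

    def summary(self) -> pd.DataFrame:
        tab = self.odds_ratios()
        tab["predictor_p"] = tab["predictor"].map(self.predictor_p)
        return tab

    def __str__(self) -> str:
        lines = [f"logistic fit, n = {self.n_used}"]
        for _, r in self.summary().iterrows():
            lines.append(
                f"  {r['term']:<28s} OR {r['odds_ratio']:5.2f} "
                f"({r['ci_low']:.2f}-{r['ci_high']:.2f})  p[{r['predictor']}]={r['predictor_p']:.3f}"
            )
        return "\n".join(lines)


def fit_univariate(cohort: pd.DataFrame, predictor: str, outcome: str = "overweight"):
    """Univariate logistic fit of the outcome on one predictor."""
    return CohortLogit(cohort, [predictor], outcome=outcome).fit()


def backward_select(
    cohort: pd.DataFrame,
    candidates: list,
    p_exclude: float = 0.10,
    outcome: str = "overweight",
    criterion: str = "lr",
):
    """Backward elimination of candidate predictors.

    At each step the model is refit on records complete for the *currently
    included* predictors; the predictor with the largest exclusion p-value is
    removed while that p-value exceeds ``p_exclude``.  Exclusion p-values are
    likelihood-ratio by default (``criterion='wald'`` for joint Wald).  Ties
    are broken by candidate order.  Returns ``(results, SelectionTrace)``;
    with every predictor removed, results is None and a warning is issued.
    """
    if not candidates:
        raise ValueError("candidate set must not be empty")
    included = list(candidates)
    trace = SelectionTrace()
    results = None
    while included:
        results = CohortLogit(cohort, included, outcome=outcome).fit()
        pvals = results.predictor_p if criterion == "lr" else results.wald_predictor_p()
        worst = max(included, key=lambda p: pvals[p])
        if pvals[worst] > p_exclude:
            trace.steps.append((worst, float(pvals[worst])))
            included.remove(worst)
            results = None
        else:
            break
    if results is None:
        import warnings

        warnings.warn("all predictors removed; returning intercept-only fit", stacklevel=2)
    trace.final_terms = list(included)
    return results, trace


def screen_interactions(
    results: LogisticFitResults,
    cohort: pd.DataFrame,
    p_include: float = 0.05,
    min_cell_events: int = 5,
):
    """Test pairwise interactions among the fitted main effects one at a time
    (likelihood-ratio); refit with all those reaching ``p_include``.

    Interactions whose exposed-by-exposed cell carries fewer than
    ``min_cell_events`` outcome events are skipped with a logged note.
    Returns ``(results, list of (pair, p))`` with the original results if no
    interaction qualifies.
    """
    model = results.model
    preds = model.predictors
    if len(preds) < 2:
        return results, []
    outcome = model.outcome
    tested = []
    selected = []
    base_cols = [outcome] + preds
    for i in range(len(preds)):
        for j in range(i + 1, len(preds)):
            pair = (preds[i], preds[j])
            df = cohort.dropna(subset=base_cols)
            y = df[outcome].astype(float)
            nonref = (
                (df[pair[0]].astype(str) != PREDICTOR_LEVELS.get(pair[0], ["?"])[0])
                & (df[pair[1]].astype(str) != PREDICTOR_LEVELS.get(pair[1], ["?"])[0])
            )
            if y[nonref].sum() < min_cell_events:
                import logging

                logging.getLogger(__name__).info(
                    "interaction %s skipped: fewer than %d events", pair, min_cell_events
                )
                continue
            try:
                full = CohortLogit(cohort, preds, outcome=outcome, interactions=[pair]).fit()
                reduced = CohortLogit(cohort, preds, outcome=outcome).fit()
            except SeparationError:
                import logging

                logging.getLogger(__name__).info(
                    "interaction %s skipped: not estimable (sparse cells)", pair
                )
                continue
            n_int = len(full.terms) - len(reduced.terms)
            lr = 2.0 * (full.llf - reduced.llf)
            p = float(stats.chi2.sf(max(lr, 0.0), df=n_int))
            tested.append((pair, p))
            if p < p_include:
                selected.append(pair)
    if not selected:
        return results, tested
    final = CohortLogit(cohort, preds, outcome=outcome, interactions=selected).fit()
    return final, tested
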