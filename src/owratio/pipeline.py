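"""End-to-end orchestration: classification -> validation -> risk models ->
standardization -> empirical Bayes -> optional imputation, with a run log
that records every setting in effect so the analysis can be re-executed
identically."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import standardize as _std
from .cohort import attach_strata, derive_categories, completeness_report
from .eb import PoissonGammaModel
from .growth import GrowthReference, SdsCutoffs, classify_lga, compute_sds
from .impute import ImputationConfig, imputed_eb_analysis
from .risk import backward_select, fit_univariate, screen_interactions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "classify_cohort", "run_full", "ReportBundle"]

DEFAULT_CANDIDATES = [
    "sex",
    "lga",
    "mother_smoking",
    "mother_bmi_cat",
    "father_bmi_cat",
    "education",
]


@dataclass
class PipelineConfig:
    """All settings of a full run; every default is written to the run log."""

    cutoffs: SdsCutoffs = field(default_factory=SdsCutoffs)
    candidates: list = field(default_factory=lambda: list(DEFAULT_CANDIDATES))
    p_exclude: float = 0.10
    p_include: float = 0.05
    crude_adjust: list = field(default_factory=lambda: list(_std.CRUDE_ADJUST))
    eb_method: str = "moments"
    selection_criterion: str = "lr"
    run_imputation: bool = False
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_exclude < 1 or not 0 < self.p_include < 1:
            raise ValueError("selection thresholds must lie in (0, 1)")

    def settings(self) -> dict:
        return {
            "cutoffs": {
                "boys": self.cutoffs.boys_cutoff,
                "girls": self.cutoffs.girls_cutoff,
                "lga": self.cutoffs.lga_cutoff,
            },
            "candidates": list(self.candidates),
            "p_exclude": self.p_exclude,
            "p_include": self.p_include,
            "crude_adjust": list(self.crude_adjust),
            "eb_method": self.eb_method,
            "selection_criterion": self.selection_criterion,
            "run_imputation": self.run_imputation,
            "imputation": {
                "m": self.imputation.m,
                "iterations": self.imputation.iterations,
                "seed": self.imputation.seed,
            },
            "seed": self.seed,
        }


def classify_cohort(
    cohort: pd.DataFrame,
    reference: GrowthReference,
    cutoffs: SdsCutoffs | None = None,
) -> pd.DataFrame:
    """Append bmi_sds, overweight and lga columns to a raw cohort frame."""
    cutoffs = cutoffs or SdsCutoffs()
    out = cohort.copy()
    sds = np.full(len(out), np.nan)
    for sex in ("male", "female"):
        m = (out["sex"] == sex).to_numpy()
        if m.any():
            sds[m] = compute_sds(
                out.loc[m, "bmi"].to_numpy(dtype=float),
                out.loc[m, "exam_age"].to_numpy(dtype=float),
                sex,
                reference,
            )
    out["bmi_sds"] = sds
    cut = np.where(out["sex"] == "male", cutoffs.boys_cutoff, cutoffs.girls_cutoff)
    ow = pd.array(sds > cut, dtype="boolean")
    ow[np.isnan(sds)] = pd.NA
    out["overweight"] = ow
    lga_flag = classify_lga(out["birthweight_sds"].to_numpy(dtype=float), cutoffs)
    out["lga"] = pd.Series(lga_flag).map({True: "yes", False: "no"}, na_action="ignore").values
    return out


@dataclass
class ReportBundle:
    """Everything a full pipeline run produces."""

    cohort: pd.DataFrame
    completeness: pd.DataFrame
    univariate: pd.DataFrame
    selection: object
    final_fit: object
    interactions: list
    cor: object
    aor: object
    cor_eb: object
    aor_eb: object
    imputed: object
    settings: dict
    timings: dict

    def tables(self) -> dict:
        out = {
            "completeness": self.completeness,
            "univariate": self.univariate,
            "multivariate": self.final_fit.summary() if self.final_fit is not None else None,
            "cor": self.cor.summary(),
            "aor": self.aor.summary(),
            "cor_eb": self.cor_eb.summary(),
            "aor_eb": self.aor_eb.summary(),
        }
        if self.imputed is not None:
            out["imputed"] = self.imputed.summary
        return {k: v for k, v in out.items() if v is not None}

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, tab in self.tables().items():
            tab.to_csv(outdir / f"{name}.csv", index=False)
        log = {"settings": self.settings, "timings": self.timings}
        if self.selection is not None:
            log["selection_steps"] = [[p, float(v)] for p, v in self.selection.steps]
            log["selected"] = list(self.selection.final_terms)
        (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))


def run_full(
    cohort: pd.DataFrame,
    parishes: pd.DataFrame,
    reference: GrowthReference,
    config: PipelineConfig | None = None,
) -> ReportBundle:
    """Execute the whole analysis chain on a raw cohort."""
    config = config or PipelineConfig()
    timings = {}

    def stage(name):
        logger.info("stage %s", name)
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    stage("classify")
    df = classify_cohort(cohort, reference, config.cutoffs)
    df = derive_categories(df)
    df = attach_strata(df, parishes)
    analysed = df[df["overweight"].notna()].copy()
    analysed["overweight"] = analysed["overweight"].astype(bool)
    logger.info(
        "%d of %d children have outcome data; %d geo-coded",
        len(analysed), len(df), int(analysed["stratum"].notna().sum()),
    )
    done("classify")

    stage("validate")
    completeness = completeness_report(analysed)
    done("validate")

    stage("fit")
    uni_rows = []
    for pred in config.candidates:
        res = fit_univariate(analysed, pred)
        tab = res.summary()
        tab.insert(0, "n_used", res.n_used)
        uni_rows.append(tab)
    univariate = pd.concat(uni_rows, ignore_index=True)
    final_fit, trace = backward_select(
        analysed, config.candidates, config.p_exclude, criterion=config.selection_criterion
    )
    interactions = []
    if final_fit is not None and len(trace.final_terms) >= 2:
        final_fit, interactions = screen_interactions(final_fit, analysed, config.p_include)
    done("fit")

    stage("standardize")
    selected = trace.final_terms or list(_std.FULL_ADJUST)
    cor = _std.IndirectStandardization(
        analysed, config.crude_adjust, kind="crude", rate_cohort=analysed
    ).fit()
    aor = _std.IndirectStandardization(analysed, selected, kind="adjusted").fit()
    done("standardize")

    stage("eb")
    cor_eb = PoissonGammaModel.from_standardization(cor).fit(method=config.eb_method)
    aor_eb = PoissonGammaModel.from_standardization(aor).fit(method=config.eb_method)
    done("eb")

    imputed = None
    if config.run_imputation:
        stage("impute")
        imputed = imputed_eb_analysis(
            analysed, config.imputation, selected, eb_method=config.eb_method
        )
        done("impute")

    return ReportBundle(
        cohort=df,
        completeness=completeness,
        univariate=univariate,
        selection=trace,
        final_fit=final_fit,
        interactions=interactions,
        cor=cor,
        aor=aor,
        cor_eb=cor_eb,
        aor_eb=aor_eb,
        imputed=imputed,
        settings=config.settings(),
        timings=timings,
    )
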