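"""End-to-end orchestration: main, stratified and sensitivity analyses.

A run executes score -> eligibility filters -> response weights ->
chained imputation with mode pooling -> design matrix -> Gibbs fit ->
effect table, deterministically for a fixed plan and seed.  Stratified
analyses refit the identical model on row subsets (UK-born vs not;
household income dichotomised at the cohort median, exact-median rows
going to the lower stratum) with White participants within the stratum
as the reference.  Sensitivity analyses re-run the main model without
weights, on complete cases only, or restricted to persons responding in
every exposure period.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import design as design_mod
from .design import DEFAULT_PERIODS, ETHNICITIES, ExposurePeriod
from .ghq import add_ghq_totals
from .impute import ImputationConfig, chained_imputation, pool_by_mode
from .its_model import (
    ITSModelSpec,
    PosteriorSummary,
    build_design_matrix,
    fit_bayes_its,
    format_effect_table,
    summarize_effects,
)
from .synthetic_cohort import MASKABLE_COVARIATES
from .weights import attach_weights, estimate_response_probabilities

logger = logging.getLogger(__name__)

ANALYSES = (
    "main",
    "stratify_uk_born",
    "stratify_income",
    "sens_unweighted",
    "sens_complete_case",
    "sens_all_periods",
)


@dataclass
class AnalysisPlan:
    persons: pd.DataFrame
    observations: pd.DataFrame
    model: ITSModelSpec = field(default_factory=ITSModelSpec)
    imputation: ImputationConfig = field(default_factory=ImputationConfig)
    periods: list[ExposurePeriod] = field(default_factory=lambda: list(DEFAULT_PERIODS))
    analyses: tuple[str, ...] = ("main",)
    out_dir: Path | None = None
    seed: int = 0


@dataclass
class PipelineResult:
    effects: pd.DataFrame
    effects_formatted: pd.DataFrame
    posterior: PosteriorSummary
    exclusion_log: pd.DataFrame
    weight_table: pd.DataFrame
    pooled: pd.DataFrame
    n_rows: int
    n_persons: int


def _seeded(plan: AnalysisPlan) -> tuple[ITSModelSpec, ImputationConfig]:
    return (
        replace(plan.model, seed=plan.seed),
        replace(plan.imputation, seed=plan.seed),
    )


def _prepare_rows(plan: AnalysisPlan) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Common front end: score, filter, return (rows, cohort persons, log)."""
    obs = add_ghq_totals(plan.observations)
    rows, log = design_mod.apply_eligibility_filters(plan.persons, obs, plan.periods)
    if rows.empty:
        raise RuntimeError("stage 'filter': no rows survive the eligibility filters")
    cohort = (
        rows[["person_id", "stratum", "ethnicity"]]
        .drop_duplicates("person_id")
        .reset_index(drop=True)
    )
    return rows, cohort, log.to_frame()


def _impute_pool(rows: pd.DataFrame, imp: ImputationConfig) -> pd.DataFrame:
    variables = imp.variables or [v for v in MASKABLE_COVARIATES if v in rows.columns]
    if not rows[variables].isna().any().any():
        pooled = rows.copy()
        for v in variables:
            pooled[f"{v}_imputed"] = False
        return pooled
    imputed = chained_imputation(rows, imp)
    return pool_by_mode(imputed, rows, variables)


def _fit(pooled: pd.DataFrame, spec: ITSModelSpec) -> tuple[pd.DataFrame, PosteriorSummary]:
    dm = build_design_matrix(pooled, spec)
    posterior = fit_bayes_its(dm, spec)
    effects = summarize_effects(posterior, spec)
    return effects, posterior


def run_main(
    plan: AnalysisPlan,
    *,
    weight_mode: str = "weighted",
    restrict: str | None = None,
) -> PipelineResult:
    """Run the primary analysis (or a sensitivity variant of it).

    ``restrict`` is used internally by :func:`run_sensitivity`
    ("complete_case" or "all_periods").
    """
    model, imp = _seeded(plan)
    rows, cohort, log = _prepare_rows(plan)

    skip_imputation = False
    if restrict == "complete_case":
        covs = [v for v in MASKABLE_COVARIATES if v in rows.columns]
        incomplete_persons = rows.loc[
            rows[covs].isna().any(axis=1), "person_id"
        ].unique()
        rows = rows[~rows["person_id"].isin(incomplete_persons)]
        cohort = cohort[~cohort["person_id"].isin(incomplete_persons)]
        skip_imputation = True
    elif restrict == "all_periods":
        per_person = rows.groupby("person_id")["period"].nunique()
        keep = per_person.index[per_person == len(plan.periods)]
        rows = rows[rows["person_id"].isin(keep)]
        cohort = cohort[cohort["person_id"].isin(keep)]
    elif restrict is not None:
        raise ValueError(f"unknown restriction {restrict!r}")
    if rows.empty:
        raise RuntimeError(f"stage 'restrict:{restrict}': no rows remain")

    weight_table = estimate_response_probabilities(
        cohort, rows, tuple(p.index for p in plan.periods)
    )
    rows = attach_weights(rows, weight_table, mode=weight_mode)

    pooled = rows.copy() if skip_imputation else _impute_pool(rows, imp)
    effects, posterior = _fit(pooled, model)
    return PipelineResult(
        effects=effects,
        effects_formatted=format_effect_table(effects),
        posterior=posterior,
        exclusion_log=log,
        weight_table=weight_table,
        pooled=pooled,
        n_rows=len(pooled),
        n_persons=pooled["person_id"].nunique(),
    )


def run_sensitivity(plan: AnalysisPlan, which: str) -> PipelineResult:
    """Sensitivity analyses: 'unweighted', 'complete_case', 'all_periods'."""
    if which == "unweighted":
        return run_main(plan, weight_mode="unweighted")
    if which in ("complete_case", "all_periods"):
        return run_main(plan, restrict=which)
    raise ValueError(f"unknown sensitivity analysis {which!r}")


def run_stratified(
    plan: AnalysisPlan, stratifier: str
) -> dict[str, PipelineResult]:
    """Refit the identical model within strata of an effect modifier.

    ``uk_born`` splits on the (imputed) UK-born indicator; ``income``
    splits household income at the cohort median band, the exact-median
    band going to the lower stratum.  Each stratum is refitted
    independently with White participants inside it as the reference.
    """
    if stratifier not in ("uk_born", "income"):
        raise ValueError(f"unknown stratifier {stratifier!r}")
    model, imp = _seeded(plan)
    rows, cohort, log = _prepare_rows(plan)
    weight_table = estimate_response_probabilities(
        cohort, rows, tuple(p.index for p in plan.periods)
    )
    rows = attach_weights(rows, weight_table, mode="weighted")
    pooled = _impute_pool(rows, imp)

    if stratifier == "uk_born":
        masks = {
            "uk_born": pooled["uk_born"] == 1,
            "non_uk_born": pooled["uk_born"] == 0,
        }
    else:
        median_band = pooled["income_band"].median()
        masks = {
            "low_income": pooled["income_band"] <= median_band,
            "high_income": pooled["income_band"] > median_band,
        }

    results = {}
    for name, mask in masks.items():
        sub = pooled[mask]
        if sub.empty:
            raise RuntimeError(f"stratum {name!r} is empty")
        effects, posterior = _fit(sub.reset_index(drop=True), model)
        results[name] = PipelineResult(
            effects=effects,
            effects_formatted=format_effect_table(effects),
            posterior=posterior,
            exclusion_log=log,
            weight_table=weight_table,
            pooled=sub,
            n_rows=len(sub),
            n_persons=sub["person_id"].nunique(),
        )
    return results


# ---------------------------------------------------------------------------
# descriptive (Table-1 shaped) reporting
# ---------------------------------------------------------------------------


def pct(n: float, d: float) -> float:
    """Percentage n/d on the 0–100 scale (NaN when d == 0)."""
    return 100.0 * n / d if d else float("nan")


@dataclass
class DescriptiveTable:
    categorical: pd.DataFrame  # characteristic, level, ethnicity, n, pct, pct_nonmissing
    numeric: pd.DataFrame  # characteristic, ethnicity, median/IQR or mean/SD
    tests: pd.DataFrame  # characteristic, ethnicity, test, p


def make_descriptive_table(
    persons: pd.DataFrame,
    rows: pd.DataFrame,
    periods: list[ExposurePeriod] | None = None,
) -> DescriptiveTable:
    """Per-ethnicity cohort description in the shape of a baseline table.

    Counts and percentages for each categorical characteristic (both the
    column-total and the non-missing denominator are reported), medians
    with IQRs for count-like variables, the pre-interruption GHQ-12 mean
    (SD), response behaviour, and comparison tests against the White
    group (chi-square for categoricals, Kruskal-Wallis for count-like
    variables, Welch t for baseline GHQ).  The tests are descriptive
    annotations, not the inferential core.
    """
    periods = DEFAULT_PERIODS if periods is None else periods
    cohort_ids = rows["person_id"].unique()
    pers = persons[persons["person_id"].isin(cohort_ids)].copy()
    # person-level covariate snapshot: first analysis row per person
    first = rows.sort_values(["person_id", "interview_date"]).groupby(
        "person_id", as_index=False
    ).first()
    covs = [v for v in MASKABLE_COVARIATES if v in first.columns]
    pers = pers.drop(columns=[c for c in covs if c in pers.columns])
    pers = pers.merge(first[["person_id"] + covs], on="person_id", how="left")
    pers["age_at_interruption"] = 2014 - pers["birth_year"]

    groups = [e for e in ETHNICITIES if e in set(pers["ethnicity"])]
    n_by_group = pers.groupby("ethnicity")["person_id"].nunique()

    cat_records, num_records, test_records = [], [], []

    def add_categorical(char: str, series_name: str):
        for g in groups + ["Total"]:
            sub = pers if g == "Total" else pers[pers["ethnicity"] == g]
            col = sub[series_name]
            n_nonmiss = col.notna().sum()
            for lev in sorted(col.dropna().unique()):
                n = int((col == lev).sum())
                cat_records.append(
                    {
                        "characteristic": char,
                        "level": lev,
                        "ethnicity": g,
                        "n": n,
                        "pct": pct(n, len(sub)),
                        "pct_nonmissing": pct(n, n_nonmiss),
                    }
                )
            n_missing = int(col.isna().sum())
            cat_records.append(
                {
                    "characteristic": char,
                    "level": "missing",
                    "ethnicity": g,
                    "n": n_missing,
                    "pct": pct(n_missing, len(sub)),
                    "pct_nonmissing": float("nan"),
                }
            )
        white = pers[pers["ethnicity"] == "White"]
        for g in groups:
            if g == "White":
                continue
            sub = pers[pers["ethnicity"] == g]
            tbl = pd.crosstab(
                pd.concat([white[series_name], sub[series_name]]),
                np.r_[np.zeros(len(white)), np.ones(len(sub))],
            )
            if tbl.shape[0] > 1 and (tbl.to_numpy() > 0).all():
                p = stats.chi2_contingency(tbl)[1]
            else:
                p = float("nan")
            test_records.append(
                {"characteristic": char, "ethnicity": g, "test": "chi2", "p": p}
            )

    def add_numeric_median(char: str, series: pd.Series):
        for g in groups + ["Total"]:
            mask = slice(None) if g == "Total" else (pers["ethnicity"] == g).to_numpy()
            vals = series.to_numpy()[mask] if g != "Total" else series.to_numpy()
            vals = vals[~pd.isna(vals)]
            num_records.append(
                {
                    "characteristic": char,
                    "ethnicity": g,
                    "statistic": "median (IQR)",
                    "center": float(np.median(vals)) if len(vals) else float("nan"),
                    "lo": float(np.percentile(vals, 25)) if len(vals) else float("nan"),
                    "hi": float(np.percentile(vals, 75)) if len(vals) else float("nan"),
                }
            )
        wvals = series[pers["ethnicity"] == "White"].dropna()
        for g in groups:
            if g == "White":
                continue
            gvals = series[pers["ethnicity"] == g].dropna()
            p = (
                stats.kruskal(wvals, gvals)[1]
                if len(wvals) and len(gvals)
                else float("nan")
            )
            test_records.append(
                {"characteristic": char, "ethnicity": g, "test": "kruskal", "p": p}
            )

    # total row
    for g in groups + ["Total"]:
        n = len(pers) if g == "Total" else int(n_by_group.get(g, 0))
        cat_records.append(
            {
                "characteristic": "total",
                "level": "",
                "ethnicity": g,
                "n": n,
                "pct": pct(n, len(pers)),
                "pct_nonmissing": pct(n, len(pers)),
            }
        )

    add_numeric_median("age", pers["age_at_interruption"])
    add_categorical("sex", "sex")
    for cov in covs:
        if cov == "n_children":
            add_numeric_median("n_children", pers[cov])
        else:
            add_categorical(cov, cov)

    responses = rows.groupby("person_id").size().reindex(pers["person_id"]).fillna(0)
    responses.index = pers.index
    add_numeric_median("responses", responses)

    per_person_periods = rows.groupby("person_id")["period"].nunique()
    all_periods = per_person_periods.reindex(pers["person_id"]).fillna(0) == len(periods)
    all_periods.index = pers.index
    pers["_all_periods"] = all_periods.astype(int)
    add_categorical("present_in_each_period", "_all_periods")

    complete = ~rows[covs].isna().any(axis=1)
    person_complete = complete.groupby(rows["person_id"]).all()
    pers["_complete_covariates"] = (
        person_complete.reindex(pers["person_id"]).fillna(False).to_numpy().astype(int)
    )
    add_categorical("complete_covariate_data", "_complete_covariates")

    # baseline-period GHQ mean (SD)
    base = rows[rows["period"] == periods[0].index]
    base_by_person = base.groupby("person_id").agg(
        ghq=("ghq_total", "mean"), ethnicity=("ethnicity", "first")
    )
    for g in groups + ["Total"]:
        vals = (
            base_by_person["ghq"]
            if g == "Total"
            else base_by_person.loc[base_by_person["ethnicity"] == g, "ghq"]
        )
        num_records.append(
            {
                "characteristic": "baseline_ghq",
                "ethnicity": g,
                "statistic": "mean (SD)",
                "center": float(vals.mean()) if len(vals) else float("nan"),
                "lo": float("nan"),
                "hi": float(vals.std(ddof=1)) if len(vals) > 1 else float("nan"),
            }
        )
    wvals = base_by_person.loc[base_by_person["ethnicity"] == "White", "ghq"]
    for g in groups:
        if g == "White":
            continue
        gvals = base_by_person.loc[base_by_person["ethnicity"] == g, "ghq"]
        p = (
            stats.ttest_ind(wvals, gvals, equal_var=False)[1]
            if len(wvals) > 1 and len(gvals) > 1
            else float("nan")
        )
        test_records.append(
            {"characteristic": "baseline_ghq", "ethnicity": g, "test": "t", "p": p}
        )

    return DescriptiveTable(
        categorical=pd.DataFrame(cat_records),
        numeric=pd.DataFrame(num_records),
        tests=pd.DataFrame(test_records),
    )


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------


def write_result(
    result: PipelineResult,
    out_dir: str | Path,
    name: str,
    save_draws: bool = False,
) -> None:
    """Write one analysis' tables (and optionally raw draws) as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.effects.to_csv(out / f"{name}_effects.csv", float_format="%.6f")
    result.effects_formatted.to_csv(out / f"{name}_effects_formatted.csv")
    result.posterior.table.to_csv(out / f"{name}_posterior.csv", float_format="%.6f")
    result.exclusion_log.to_csv(out / f"{name}_exclusions.csv", index=False)
    result.weight_table.to_csv(
        out / f"{name}_weights.csv", index=False, float_format="%.6f"
    )
    if save_draws:
        result.posterior.draws_frame().to_csv(
            out / f"{name}_draws.csv", index=False, float_format="%.6g"
        )


def run_plan(plan: AnalysisPlan) -> dict[str, PipelineResult]:
    """Execute every analysis named in the plan; optionally write CSVs."""
    results: dict[str, PipelineResult] = {}
    for analysis in plan.analyses:
        if analysis == "main":
            results["main"] = run_main(plan)
        elif analysis.startswith("stratify_"):
            strat = analysis.removeprefix("stratify_")
            for sub, res in run_stratified(plan, strat).items():
                results[f"{analysis}.{sub}"] = res
        elif analysis.startswith("sens_"):
            results[analysis] = run_sensitivity(plan, analysis.removeprefix("sens_"))
        else:
            raise ValueError(f"unknown analysis {analysis!r}")
    if plan.out_dir is not None:
        for name, res in results.items():
            write_result(res, plan.out_dir, name.replace(".", "_"))
    return results
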