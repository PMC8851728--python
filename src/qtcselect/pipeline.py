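"""End-to-end pipeline: simulate -> correct -> filter -> optimize -> assess -> limits -> validate.

Runs every stage from a single :class:`PipelineConfig`, writing seven
CSV/JSON artifacts plus a manifest, all deterministic for a fixed
config and seed:

* ``demographics.csv``          per-sex summaries with t / chi-square p-values
* ``correction_methods.json``   the four cohort-optimal correction fits
* ``slope_assessment.csv``      QTc~RR slopes per formula and sex, with ranking
* ``normal_limits.csv``         LLN/ULN with bootstrap CIs
* ``diagnostic_metrics.csv``    sensitivity/specificity/PPV/NPV of QTc>ULN
* ``cox_models.csv``            unadjusted and age+HR-adjusted hazard ratios
* ``stepwise_competition.json`` the backward-stepwise flag competition

Because the prolongation exposure (QTc above the sex-specific upper
limit of normal) only exists after the limits stage, the generator needs
a provisional exposure to attach excess hazard to: the pipeline flags
subjects whose Bazett-corrected QT exceeds the sex-specific 95th
percentile of the raw cohort and feeds that flag to the survival stage
with the configured true hazard ratio.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import __version__
from .assessment import qtc_rr_slope, rank_formulas
from .filters import apply_eligibility, select_healthy
from .formulas import SIX_FORMULAS, correct_qt, correct_qt_batch
from .limits import normal_limits_table
from .optimal import (
    apply_custom_correction,
    fit_linear_hr,
    fit_linear_rr,
    fit_loglog_exponent,
    grid_search_exponent,
)
from .synthetic import GeneratorConfig, SurvivalConfig, generate_cohort, generate_survival
from .validation import classify_prolonged, cox_fit, diagnostic_metrics, stepwise_competition

__all__ = ["PipelineConfig", "run_pipeline", "summarize_demographics", "load_pipeline_config"]

logger = logging.getLogger("qtcselect")

STAGES = ("simulate", "correct", "filter", "optimize", "assess", "limits", "validate")

ARTIFACTS = {
    "demographics": "demographics.csv",
    "correction_methods": "correction_methods.json",
    "slope_assessment": "slope_assessment.csv",
    "normal_limits": "normal_limits.csv",
    "diagnostic_metrics": "diagnostic_metrics.csv",
    "cox_models": "cox_models.csv",
    "stepwise_competition": "stepwise_competition.json",
}

CONTINUOUS_VARS = [("age", 1.0), ("hr", 1.0), ("qrs", 1.0), ("qt", 1000.0), ("survival_days", 1.0)]
FLAG_VARS = ["cvd_history", "medical_condition", "qt_drug", "death", "cardiac_death"]


@dataclass(frozen=True)
class PipelineConfig:
    """One config to drive every stage."""

    generator: GeneratorConfig = field(default_factory=lambda: GeneratorConfig(n_subjects=7071))
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 1
    out_dir: str = "results"
    stages: tuple[str, ...] = STAGES
    n_boot: int = 2000
    pooled_t: bool = True

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.generator.validate()
        self.survival.validate()


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Read a pipeline config from YAML or JSON."""
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = dict(data or {})
    from .synthetic import _dataclass_from_mapping  # shared coercion helper

    if "generator" in data:
        data["generator"] = _dataclass_from_mapping(GeneratorConfig, data["generator"])
    if "survival" in data:
        data["survival"] = _dataclass_from_mapping(SurvivalConfig, data["survival"])
    if "stages" in data:
        data["stages"] = tuple(data["stages"])
    cfg = PipelineConfig(**data)
    cfg.validate()
    return cfg


def summarize_demographics(cohort: pd.DataFrame, pooled_t: bool = True) -> pd.DataFrame:
    """Per-sex means±SD and counts(%) with between-sex test p-values.

    Continuous variables are compared by a two-sample t test (pooled
    variance by default, Welch otherwise); binary flags by a Pearson
    chi-square without continuity correction.  Zero-variance comparisons
    yield a NaN p-value.
    """
    males = cohort.loc[cohort["male"] == 1]
    females = cohort.loc[cohort["male"] == 0]
    if len(males) == 0 or len(females) == 0:
        raise ValueError("both sex strata must be non-empty")

    rows = []
    for var, scale in CONTINUOUS_VARS:
        if var not in cohort.columns:
            continue
        x = males[var].to_numpy(dtype=float) * scale
        y = females[var].to_numpy(dtype=float) * scale
        if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
            p = 1.0 if x.mean() == y.mean() else float("nan")
        else:
            p = float(scipy.stats.ttest_ind(x, y, equal_var=pooled_t).pvalue)
        rows.append(
            {
                "variable": var,
                "kind": "continuous",
                "male": f"{x.mean():.2f} ± {x.std(ddof=1):.2f}",
                "female": f"{y.mean():.2f} ± {y.std(ddof=1):.2f}",
                "p_value": p,
            }
        )
    for var in FLAG_VARS:
        if var not in cohort.columns:
            continue
        a = int(males[var].sum())
        b = int(females[var].sum())
        table = np.array([[a, len(males) - a], [b, len(females) - b]])
        if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
            p = float("nan")
        else:
            p = float(scipy.stats.chi2_contingency(table, correction=False).pvalue)
        rows.append(
            {
                "variable": var,
                "kind": "count",
                "male": f"{a} ({100.0 * a / len(males):.1f})",
                "female": f"{b} ({100.0 * b / len(females):.1f})",
                "p_value": p,
            }
        )
    return pd.DataFrame(rows)


def _provisional_exposure(cohort: pd.DataFrame) -> pd.Series:
    """Flag the sex-specific top 5% of Bazett-corrected QT in the raw cohort."""
    qtc = correct_qt(
        cohort["qt"].to_numpy(dtype=float),
        cohort["rr"].to_numpy(dtype=float),
        cohort["male"].to_numpy(dtype=float),
        SIX_FORMULAS[0],  # bazett
    )
    flag = np.zeros(len(cohort), dtype=int)
    for sex_flag in (0, 1):
        m = cohort["male"].to_numpy() == sex_flag
        if m.sum() >= 20:
            cut = np.quantile(qtc[m], 0.95, method="weibull")
            flag[m] = (qtc[m] > cut).astype(int)
    return pd.Series(flag, index=cohort.index, name="provisional_prolonged")


def _fit_to_dict(fit) -> dict:
    d = dataclasses.asdict(fit)
    return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write artifacts; returns the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "qtcselect",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "artifacts": {},
        "row_counts": {},
        "skipped": [],
    }
    seeds = np.random.SeedSequence(config.seed).generate_state(4) % (2**31)
    gen_cfg = dataclasses.replace(config.generator, seed=int(seeds[0]))
    surv_cfg = dataclasses.replace(config.survival, seed=int(seeds[1]))

    def stage_enabled(name: str) -> bool:
        if name in config.stages:
            return True
        manifest["skipped"].append(name)
        return False

    def timed(name: str):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def write_csv(key: str, df: pd.DataFrame) -> None:
        path = out_dir / ARTIFACTS[key]
        df.to_csv(path, index=False, float_format="%.6g")
        manifest["artifacts"][key] = path.name
        manifest["row_counts"][key] = len(df)

    def write_json(key: str, obj) -> None:
        path = out_dir / ARTIFACTS[key]
        path.write_text(json.dumps(obj, indent=1, sort_keys=True, allow_nan=True))
        manifest["artifacts"][key] = path.name

    current_stage = "simulate"
    try:
        # ---- simulate ----
        t0 = timed("simulate")
        cohort = generate_cohort(gen_cfg)
        cohort["provisional_prolonged"] = _provisional_exposure(cohort)
        surv_cfg = dataclasses.replace(surv_cfg, exposure_column="provisional_prolonged")
        cohort = generate_survival(cohort, surv_cfg)
        logger.info("simulate done in %.2fs (n=%d)", time.perf_counter() - t0, len(cohort))

        # ---- correct ----
        current_stage = "correct"
        t0 = timed("correct")
        cohort = correct_qt_batch(cohort, SIX_FORMULAS)
        qtc_cols = [f"qtc_{f.name}" for f in SIX_FORMULAS]
        logger.info("correct done in %.2fs", time.perf_counter() - t0)

        # ---- filter ----
        current_stage = "filter"
        eligible, elig_report = apply_eligibility(cohort)
        healthy, healthy_report = select_healthy(eligible)
        manifest["row_counts"]["eligible"] = len(eligible)
        manifest["row_counts"]["healthy"] = len(healthy)
        manifest["filter_reports"] = {
            "eligibility": elig_report.to_dict(),
            "healthy": healthy_report.to_dict(),
        }

        demo = summarize_demographics(eligible, pooled_t=config.pooled_t)
        write_csv("demographics", demo)

        # ---- optimize ----
        current_stage = "optimize"
        if stage_enabled("optimize"):
            t0 = timed("optimize")
            lin_rr = fit_linear_rr(healthy)
            lin_hr = fit_linear_hr(healthy)
            loglog = {s: fit_loglog_exponent(healthy, s) for s in ("male", "female")}
            grid = grid_search_exponent(healthy)
            methods = {
                "linear_rr": _fit_to_dict(lin_rr),
                "linear_hr": _fit_to_dict(lin_hr),
                "loglog": {s: _fit_to_dict(r) for s, r in loglog.items()},
                "grid": {
                    "d": grid.d,
                    "abs_corr_at_d": grid.abs_corr_at_d,
                    "trace": grid.trace.round(8).to_dict("list"),
                },
            }
            for name, fit in (("linear_rr", lin_rr), ("linear_hr", lin_hr),
                              ("loglog", loglog), ("grid", grid)):
                _, r2 = apply_custom_correction(healthy, fit)
                methods[name if name != "loglog" else "loglog"]["post_correction_r2"] = r2
            write_json("correction_methods", methods)
            logger.info("optimize done in %.2fs", time.perf_counter() - t0)

        # ---- assess ----
        current_stage = "assess"
        if stage_enabled("assess"):
            t0 = timed("assess")
            rows = []
            for sex in ("male", "female"):
                assessments = [qtc_rr_slope(healthy, col, sex) for col in qtc_cols]
                ranked = rank_formulas(assessments)
                for rank, a in enumerate(ranked, start=1):
                    rows.append(
                        {
                            "sex": sex,
                            "formula": a.formula,
                            "rank": rank,
                            "slope_ms_per_s": a.slope,
                            "slope_ci_low": a.slope_ci_95[0],
                            "slope_ci_high": a.slope_ci_95[1],
                            "intercept_ms": a.intercept,
                            "intercept_ci_low": a.intercept_ci_95[0],
                            "intercept_ci_high": a.intercept_ci_95[1],
                            "r_squared": a.r_squared,
                            "n": a.n,
                        }
                    )
            write_csv("slope_assessment", pd.DataFrame(rows))
            logger.info("assess done in %.2fs", time.perf_counter() - t0)

        # ---- limits ----
        current_stage = "limits"
        limits_by_formula: dict[str, dict] = {}
        if stage_enabled("limits"):
            t0 = timed("limits")
            lims = normal_limits_table(healthy, qtc_cols, n_boot=config.n_boot, seed=int(seeds[2]))
            rows = []
            for lim in lims:
                limits_by_formula.setdefault(lim.formula, {})[lim.sex] = lim
                rows.append(
                    {
                        "formula": lim.formula,
                        "sex": lim.sex,
                        "lln_ms": round(lim.lln, 2),
                        "lln_ci_low": round(lim.lln_ci[0], 2),
                        "lln_ci_high": round(lim.lln_ci[1], 2),
                        "uln_ms": round(lim.uln, 2),
                        "uln_ci_low": round(lim.uln_ci[0], 2),
                        "uln_ci_high": round(lim.uln_ci[1], 2),
                        "n_healthy": lim.n_healthy,
                    }
                )
            write_csv("normal_limits", pd.DataFrame(rows))
            logger.info("limits done in %.2fs", time.perf_counter() - t0)

        # ---- validate ----
        current_stage = "validate"
        if stage_enabled("validate"):
            if not limits_by_formula:
                raise RuntimeError("validate stage requires the limits stage")
            t0 = timed("validate")
            flag_cols = []
            for col in qtc_cols:
                name = col.removeprefix("qtc_")
                flag = classify_prolonged(eligible, col, limits_by_formula[name])
                eligible[flag.name] = flag
                flag_cols.append(flag.name)

            metric_rows = []
            for outcome, event_col in (("all_cause", "death"), ("cardiac", "cardiac_death")):
                for col, flag_col in zip(qtc_cols, flag_cols):
                    m = diagnostic_metrics(
                        eligible[flag_col], eligible[event_col],
                        formula=col.removeprefix("qtc_"), outcome=outcome,
                    )
                    metric_rows.append(dataclasses.asdict(m))
            write_csv("diagnostic_metrics", pd.DataFrame(metric_rows))

            cox_rows = []
            for outcome in ("all_cause", "cardiac"):
                for flag_col in flag_cols:
                    for label, covs in (("unadjusted", []), ("age_hr_adjusted", ["age", "hr"])):
                        res = cox_fit(eligible, flag_col, covariates=covs, outcome=outcome)
                        cox_rows.append(
                            {
                                "formula": flag_col.removeprefix("qtc_").removesuffix("_prolonged"),
                                "outcome": outcome,
                                "model": label,
                                "hazard_ratio": res.hazard_ratio,
                                "ci_low": res.ci_95[0],
                                "ci_high": res.ci_95[1],
                                "p_value": res.p_value,
                                "n_events": res.n_events,
                            }
                        )
            write_csv("cox_models", pd.DataFrame(cox_rows))

            stepwise_out = {}
            for outcome in ("all_cause", "cardiac"):
                sw = stepwise_competition(eligible, flag_cols, outcome=outcome)
                stepwise_out[outcome] = {
                    "retained": list(sw.retained),
                    "forced": list(sw.forced),
                    "dropped_duplicates": list(sw.dropped_duplicates),
                    "final": [dataclasses.asdict(r) for r in sw.final],
                    "trace": list(sw.trace),
                }
            write_json("stepwise_competition", stepwise_out)
            logger.info("validate done in %.2fs", time.perf_counter() - t0)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {current_stage!r}: {err}") from err

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
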