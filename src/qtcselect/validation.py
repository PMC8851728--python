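"""Mortality validation of QTc prolongation flags.

A subject is "prolonged" when the corrected QT strictly exceeds the
sex-specific upper limit of normal.  The flag is validated two ways:

* diagnostic metrics against observed mortality — sensitivity,
  specificity, PPV, NPV from the confusion matrix, in percent;
* Cox proportional-hazards models of survival time — unadjusted,
  covariate-adjusted, and a backward-stepwise competition in which all
  six formulas' flags enter one model with forced covariates (age,
  heart rate) that are never removed.

Cardiac-mortality analyses use the cause-specific hazard: non-cardiac
deaths are censored at their death time.  Ties are handled with the
Breslow approximation.  Ratios with zero denominator are reported as
NaN rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "DiagnosticMetrics",
    "CoxResult",
    "StepwiseResult",
    "classify_prolonged",
    "diagnostic_metrics",
    "cox_fit",
    "stepwise_competition",
]

OUTCOMES = ("all_cause", "cardiac")


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion-matrix metrics, each in percent (NaN when undefined)."""

    formula: str
    outcome: str
    flagged_fraction: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    tp: int
    fn: int
    fp: int
    tn: int


@dataclass(frozen=True)
class CoxResult:
    """One exposure's hazard ratio from a proportional-hazards fit."""

    exposure: str
    outcome: str
    hazard_ratio: float
    ci_95: tuple[float, float]
    p_value: float
    covariates: tuple[str, ...]
    n_events: int

    def __post_init__(self) -> None:
        if not self.hazard_ratio > 0:
            raise ValueError(f"hazard ratio must be > 0, got {self.hazard_ratio}")


@dataclass(frozen=True)
class StepwiseResult:
    """Outcome of the backward-stepwise flag competition."""

    retained: tuple[str, ...]
    final: tuple[CoxResult, ...]
    trace: tuple[dict, ...]  # one entry per step: flags in model, p-values, removal
    forced: tuple[str, ...]
    dropped_duplicates: tuple[str, ...] = ()


def _event_column(outcome: str) -> str:
    if outcome not in OUTCOMES:
        raise ValueError(f"outcome must be one of {OUTCOMES}, got {outcome!r}")
    return "death" if outcome == "all_cause" else "cardiac_death"


def classify_prolonged(cohort: pd.DataFrame, qtc_column: str, limits) -> pd.Series:
    """Binary flag: 1 iff qtc strictly exceeds the subject's sex-specific ULN.

    ``limits`` is a mapping ``{"male": NormalLimits, "female": ...}`` or an
    iterable of NormalLimits; every sex present in the cohort must have a
    limit.
    """
    if qtc_column not in cohort.columns:
        raise ValueError(f"column {qtc_column!r} not found")
    if not isinstance(limits, dict):
        limits = {lim.sex: lim for lim in limits}
    present = set()
    if (cohort["male"] == 1).any():
        present.add("male")
    if (cohort["male"] == 0).any():
        present.add("female")
    missing = present - set(limits)
    if missing:
        raise ValueError(f"no normal limits provided for: {sorted(missing)}")
    uln = np.where(
        cohort["male"].to_numpy() == 1,
        limits["male"].uln if "male" in limits else np.nan,
        limits["female"].uln if "female" in limits else np.nan,
    )
    flag = (cohort[qtc_column].to_numpy(dtype=float) > uln).astype(int)
    return pd.Series(flag, index=cohort.index, name=f"{qtc_column}_prolonged")


def diagnostic_metrics(
    flags, deaths, formula: str = "", outcome: str = "all_cause"
) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV (in %) of a binary flag vs deaths."""
    flags = np.asarray(flags, dtype=int)
    deaths = np.asarray(deaths, dtype=int)
    if flags.shape != deaths.shape:
        raise ValueError(f"length mismatch: {flags.shape} vs {deaths.shape}")
    if len(flags) == 0:
        raise ValueError("empty inputs")

    tp = int(((flags == 1) & (deaths == 1)).sum())
    fn = int(((flags == 0) & (deaths == 1)).sum())
    fp = int(((flags == 1) & (deaths == 0)).sum())
    tn = int(((flags == 0) & (deaths == 0)).sum())

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return DiagnosticMetrics(
        formula=formula,
        outcome=outcome,
        flagged_fraction=100.0 * (tp + fp) / len(flags),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        ppv=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
    )


def _fit_cox(df: pd.DataFrame, outcome: str) -> CoxPHFitter:
    event_col = _event_column(outcome)
    fitter = CoxPHFitter()
    try:
        fitter.fit(df, duration_col="survival_days", event_col=event_col)
    except ConvergenceError as err:
        raise ConvergenceError(f"Cox model failed to converge (possible separation): {err}") from err
    return fitter


def cox_fit(
    cohort: pd.DataFrame,
    exposure_column: str,
    covariates: list[str] | None = None,
    outcome: str = "all_cause",
) -> CoxResult:
    """Proportional-hazards fit of one binary exposure (plus covariates).

    Returns the exposure's hazard ratio with a Wald 95% CI and p-value.
    For ``outcome="cardiac"`` non-cardiac deaths count as censored.
    """
    covariates = list(covariates or [])
    event_col = _event_column(outcome)
    cols = [exposure_column, *covariates]
    missing = [c for c in cols + ["survival_days", event_col] if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    exposure = cohort[exposure_column].to_numpy()
    if not np.isin(exposure, (0, 1)).all():
        raise ValueError(f"exposure {exposure_column!r} must be binary 0/1")
    n_events = int(cohort[event_col].sum())
    if n_events == 0:
        raise ValueError(f"no events for outcome {outcome!r}")

    df = cohort[["survival_days", event_col, *cols]]
    fitter = _fit_cox(df, outcome)
    summary = fitter.summary
    row = summary.loc[exposure_column]
    return CoxResult(
        exposure=exposure_column,
        outcome=outcome,
        hazard_ratio=float(row["exp(coef)"]),
        ci_95=(float(row["exp(coef) lower 95%"]), float(row["exp(coef) upper 95%"])),
        p_value=float(row["p"]),
        covariates=tuple(covariates),
        n_events=n_events,
    )


def stepwise_competition(
    cohort: pd.DataFrame,
    exposure_columns: list[str],
    forced: list[str] = ("age", "hr"),
    outcome: str = "all_cause",
    p_removal: float = 0.10,
) -> StepwiseResult:
    """Backward-stepwise Wald competition among prolongation flags.

    Starts from a model holding the forced covariates plus every flag;
    at each step the flag with the largest Wald p-value is removed if
    that p-value is >= ``p_removal``; stops when every remaining flag is
    below the threshold.  Forced covariates never leave the model.
    Duplicate flag columns (byte-identical, which would make the design
    singular) are dropped up front and recorded.
    """
    forced = list(forced)
    event_col = _event_column(outcome)
    missing = [
        c for c in [*exposure_columns, *forced, "survival_days", event_col]
        if c not in cohort.columns
    ]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if int(cohort[event_col].sum()) == 0:
        raise ValueError(f"no events for outcome {outcome!r}")

    flags: list[str] = []
    dropped_dup: list[str] = []
    for col in exposure_columns:
        if any(cohort[col].equals(cohort[kept]) for kept in flags):
            dropped_dup.append(col)
        else:
            flags.append(col)

    trace: list[dict] = []
    step = 0
    while True:
        df = cohort[["survival_days", event_col, *forced, *flags]]
        try:
            fitter = _fit_cox(df, outcome)
        except ConvergenceError as err:
            raise ConvergenceError(f"step {step}: {err}") from err
        pvals = {f: float(fitter.summary.loc[f, "p"]) for f in flags}
        removable = {f: p for f, p in pvals.items() if p >= p_removal}
        removed = max(removable, key=removable.get) if removable else None
        trace.append(
            {
                "step": step,
                "flags_in_model": list(flags),
                "forced": list(forced),
                "p_values": pvals,
                "removed": removed,
            }
        )
        if removed is None or len(flags) == 0:
            break
        flags.remove(removed)
        step += 1
        if not flags:
            # final forced-only model for the record
            trace.append(
                {
                    "step": step,
                    "flags_in_model": [],
                    "forced": list(forced),
                    "p_values": {},
                    "removed": None,
                }
            )
            break

    # statistics of the retained flags in the last (final-step) model
    final = tuple(
        CoxResult(
            exposure=f,
            outcome=outcome,
            hazard_ratio=float(fitter.summary.loc[f, "exp(coef)"]),
            ci_95=(
                float(fitter.summary.loc[f, "exp(coef) lower 95%"]),
                float(fitter.summary.loc[f, "exp(coef) upper 95%"]),
            ),
            p_value=float(fitter.summary.loc[f, "p"]),
            covariates=tuple(forced + [g for g in flags if g != f]),
            n_events=int(cohort[event_col].sum()),
        )
        for f in flags
    )
    return StepwiseResult(
        retained=tuple(flags),
        final=final,
        trace=tuple(trace),
        forced=tuple(forced),
        dropped_duplicates=tuple(dropped_dup),
    )
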