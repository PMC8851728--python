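"""Cohort-optimal QT corrections, derived four ways.

Given a (healthy) cohort, four classical routes to a population-specific
correction are implemented:

1. :func:`fit_linear_rr` — OLS of QT on RR and a male indicator
   (Framingham-style); the correction ``qtc1 = qt + b*(1 - rr)`` uses the
   fitted RR slope and is neutral at RR = 1 s.
2. :func:`fit_linear_hr` — OLS of QT on heart rate (Hodges-style);
   ``qtc2 = qt - b*(hr - 60)``, neutral at 60 bpm.
3. :func:`fit_loglog_exponent` — per-sex OLS of log QT on log RR; the
   slope is the power-law exponent and ``qtc3 = qt / rr**beta``.
4. :func:`grid_search_exponent` — the zero-correlation criterion: over
   the grid d = 0.301, 0.302, ..., 0.499 choose the d minimising the
   absolute Pearson correlation between ``qt / rr**d`` and rr.

All fits take QT and RR in seconds; :func:`apply_custom_correction`
returns the corrected column in milliseconds for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "LinearFitResult",
    "ExponentFitResult",
    "GridSearchResult",
    "fit_linear_rr",
    "fit_linear_hr",
    "fit_loglog_exponent",
    "grid_search_exponent",
    "apply_custom_correction",
]


@dataclass(frozen=True)
class LinearFitResult:
    """OLS fit of QT on RR (+ male) or on HR."""

    predictor: str  # "rr" or "hr"
    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    r_squared: float
    male_coeff: float | None = None
    se_male: float | None = None
    n: int = 0


@dataclass(frozen=True)
class ExponentFitResult:
    """Per-sex log-log fit; ``beta`` is the power-law exponent."""

    sex: str
    beta: float
    se_beta: float
    alpha: float  # log-scale intercept
    r_squared: float
    n: int = 0


@dataclass(frozen=True)
class GridSearchResult:
    """Zero-correlation exponent search over a fixed grid."""

    d: float
    abs_corr_at_d: float
    grid: np.ndarray
    correlations: np.ndarray

    @property
    def trace(self) -> pd.DataFrame:
        return pd.DataFrame({"d": self.grid, "corr": self.correlations})


def _require_rows(cohort: pd.DataFrame, n_min: int, what: str) -> None:
    if len(cohort) < n_min:
        raise ValueError(f"{what} requires at least {n_min} rows, got {len(cohort)}")


def _ols(y: np.ndarray, X: pd.DataFrame):
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise ValueError(
            f"rank-deficient design (constant or collinear predictors: {list(X.columns)})"
        )
    return sm.OLS(y, design).fit()


def fit_linear_rr(cohort: pd.DataFrame, include_sex: bool = True) -> LinearFitResult:
    """OLS of qt on rr (and a male indicator when ``include_sex``)."""
    _require_rows(cohort, 3, "fit_linear_rr")
    y = cohort["qt"].to_numpy(dtype=float)
    cols = {"rr": cohort["rr"].to_numpy(dtype=float)}
    if include_sex:
        male = cohort["male"].to_numpy(dtype=float)
        if len(np.unique(male)) < 2:
            raise ValueError("male indicator is constant; fit with include_sex=False")
        cols["male"] = male
    res = _ols(y, pd.DataFrame(cols))
    return LinearFitResult(
        predictor="rr",
        intercept=float(res.params["const"]),
        slope=float(res.params["rr"]),
        se_intercept=float(res.bse["const"]),
        se_slope=float(res.bse["rr"]),
        r_squared=float(res.rsquared),
        male_coeff=float(res.params["male"]) if include_sex else None,
        se_male=float(res.bse["male"]) if include_sex else None,
        n=len(cohort),
    )


def fit_linear_hr(cohort: pd.DataFrame) -> LinearFitResult:
    """OLS of qt on heart rate."""
    _require_rows(cohort, 3, "fit_linear_hr")
    y = cohort["qt"].to_numpy(dtype=float)
    hr = cohort["hr"].to_numpy(dtype=float)
    if np.ptp(hr) == 0:
        raise ValueError("hr is constant; slope undefined")
    res = _ols(y, pd.DataFrame({"hr": hr}))
    return LinearFitResult(
        predictor="hr",
        intercept=float(res.params["const"]),
        slope=float(res.params["hr"]),
        se_intercept=float(res.bse["const"]),
        se_slope=float(res.bse["hr"]),
        r_squared=float(res.rsquared),
        n=len(cohort),
    )


def fit_loglog_exponent(cohort: pd.DataFrame, sex: str) -> ExponentFitResult:
    """Per-sex OLS of log(qt) on log(rr); the slope is base-invariant."""
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    stratum = cohort.loc[cohort["male"] == (1 if sex == "male" else 0)]
    _require_rows(stratum, 3, f"fit_loglog_exponent[{sex}]")
    qt = stratum["qt"].to_numpy(dtype=float)
    rr = stratum["rr"].to_numpy(dtype=float)
    if np.any(qt <= 0) or np.any(rr <= 0):
        raise ValueError("qt and rr must be strictly positive for the log-log fit")
    res = _ols(np.log(qt), pd.DataFrame({"logrr": np.log(rr)}))
    return ExponentFitResult(
        sex=sex,
        beta=float(res.params["logrr"]),
        se_beta=float(res.bse["logrr"]),
        alpha=float(res.params["const"]),
        r_squared=float(res.rsquared),
        n=len(stratum),
    )


def grid_search_exponent(
    cohort: pd.DataFrame,
    d_min: float = 0.301,
    d_max: float = 0.499,
    step: float = 0.001,
) -> GridSearchResult:
    """Exponent minimising |corr(qt / rr**d, rr)| over the grid.

    Ties in |correlation| are broken toward the smaller d.  The full
    (d, correlation) trace is returned for inspection.
    """
    _require_rows(cohort, 3, "grid_search_exponent")
    qt = cohort["qt"].to_numpy(dtype=float)
    rr = cohort["rr"].to_numpy(dtype=float)
    if np.ptp(rr) == 0:
        raise ValueError("rr is constant; correlation with rr undefined")
    n_steps = int(round((d_max - d_min) / step)) + 1
    grid = np.round(d_min + step * np.arange(n_steps), 6)

    # corr(qt * rr**-d, rr) for all d at once: center columns, then cosine.
    qtc = qt[:, None] * rr[:, None] ** (-grid[None, :])
    qtc_c = qtc - qtc.mean(axis=0, keepdims=True)
    rr_c = rr - rr.mean()
    denom = np.sqrt((qtc_c**2).sum(axis=0)) * np.sqrt((rr_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (qtc_c * rr_c[:, None]).sum(axis=0) / denom
    corr = np.where(np.isfinite(corr), corr, 0.0)  # zero-variance qtc: treat as uncorrelated

    best = int(np.argmin(np.abs(corr)))  # argmin takes the first minimum -> smallest d
    return GridSearchResult(
        d=float(grid[best]),
        abs_corr_at_d=float(abs(corr[best])),
        grid=grid,
        correlations=corr,
    )


def apply_custom_correction(
    cohort: pd.DataFrame,
    method_result: LinearFitResult | GridSearchResult | dict[str, ExponentFitResult],
) -> tuple[pd.Series, float]:
    """Apply a fitted cohort-optimal correction; returns (qtc in ms, residual r²).

    ``method_result`` is the output of one of the four fits; the per-sex
    log-log method takes a mapping ``{"male": ..., "female": ...}``.  The
    returned r² is from the post-correction regression of qtc on rr — a
    value near zero means the correction removed the RR dependence.
    """
    qt = cohort["qt"].to_numpy(dtype=float)
    rr = cohort["rr"].to_numpy(dtype=float)

    if isinstance(method_result, LinearFitResult):
        if method_result.predictor == "rr":
            qtc = qt + method_result.slope * (1.0 - rr)
        else:
            qtc = qt - method_result.slope * (60.0 / rr - 60.0)
    elif isinstance(method_result, GridSearchResult):
        qtc = qt / rr**method_result.d
    elif isinstance(method_result, dict):
        sexes_present = {"male"} if (cohort["male"] == 1).all() else (
            {"female"} if (cohort["male"] == 0).all() else {"male", "female"}
        )
        missing = sexes_present - set(method_result)
        if missing:
            raise ValueError(f"per-sex exponents missing for: {sorted(missing)}")
        beta = np.where(
            cohort["male"].to_numpy() == 1,
            method_result.get("male", method_result.get("female")).beta,
            method_result.get("female", method_result.get("male")).beta,
        )
        qtc = qt / rr**beta
    else:
        raise TypeError(f"unsupported method result type: {type(method_result).__name__}")

    # a perfectly matched correction leaves qtc constant up to float64
    # rounding; regressing that rounding noise on rr yields garbage r², so
    # treat a relatively-constant column as fully corrected
    degenerate = np.ptp(qtc) <= 1e-9 * max(1.0, float(np.abs(qtc).max()))
    if len(cohort) >= 3 and np.ptp(rr) > 0 and not degenerate:
        res = _ols(qtc, pd.DataFrame({"rr": rr}))
        r2 = float(res.rsquared)
    elif degenerate and len(cohort) >= 3:
        r2 = 0.0
    else:
        r2 = float("nan")
    return pd.Series(1000.0 * qtc, index=cohort.index, name="qtc_custom"), r2
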