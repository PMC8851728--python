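"""Adjudication among correction formulas.

Two complementary views:

* the slope criterion — within each sex, regress QTc (ms) on RR (s); an
  ideal correction leaves QTc statistically independent of RR, so the
  formula with slope nearest zero (ties: smaller r²) ranks best.  A
  negative slope signals over-correction (QTc inflated at fast rates),
  a positive slope under-correction.
* pairwise agreement — Pearson correlation, paired-t mean differences
  and Bland-Altman bias / limits of agreement between every pair of
  corrected columns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

__all__ = ["SlopeAssessment", "AgreementSummary", "qtc_rr_slope", "rank_formulas", "pairwise_agreement"]


@dataclass(frozen=True)
class SlopeAssessment:
    """Within-sex OLS of QTc (ms) on RR (s)."""

    formula: str
    sex: str
    slope: float
    slope_ci_95: tuple[float, float]
    intercept: float
    intercept_ci_95: tuple[float, float]
    r_squared: float
    n: int


@dataclass(frozen=True)
class AgreementSummary:
    """Pairwise agreement between two corrected-QT columns (ms)."""

    pair: tuple[str, str]
    pearson_r: float
    mean_difference: float
    paired_t_p: float  # NaN when the difference has zero variance
    bias: float
    loa_low: float
    loa_high: float


def qtc_rr_slope(cohort: pd.DataFrame, qtc_column: str, sex: str) -> SlopeAssessment:
    """Fit QTc ~ RR within one sex stratum; CIs from the classical t intervals."""
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if qtc_column not in cohort.columns:
        raise ValueError(f"column {qtc_column!r} not found")
    stratum = cohort.loc[cohort["male"] == (1 if sex == "male" else 0)]
    if len(stratum) < 3:
        raise ValueError(f"stratum {sex!r} has {len(stratum)} rows; need >= 3")
    rr = stratum["rr"].to_numpy(dtype=float)
    if np.ptp(rr) == 0:
        raise ValueError("rr is constant in the stratum; slope undefined")
    y = stratum[qtc_column].to_numpy(dtype=float)
    res = sm.OLS(y, sm.add_constant(pd.DataFrame({"rr": rr}))).fit()
    ci = res.conf_int(alpha=0.05)
    name = qtc_column.removeprefix("qtc_")
    return SlopeAssessment(
        formula=name,
        sex=sex,
        slope=float(res.params["rr"]),
        slope_ci_95=(float(ci.loc["rr", 0]), float(ci.loc["rr", 1])),
        intercept=float(res.params["const"]),
        intercept_ci_95=(float(ci.loc["const", 0]), float(ci.loc["const", 1])),
        r_squared=float(res.rsquared),
        n=len(stratum),
    )


def rank_formulas(assessments: list[SlopeAssessment]) -> list[SlopeAssessment]:
    """Order by |slope| ascending, ties by smaller r², then by name.

    All assessments must come from the same sex stratum.
    """
    if not assessments:
        raise ValueError("no assessments to rank")
    sexes = {a.sex for a in assessments}
    if len(sexes) > 1:
        raise ValueError(f"mixed-sex assessments cannot be ranked together: {sorted(sexes)}")
    return sorted(assessments, key=lambda a: (abs(a.slope), a.r_squared, a.formula))


def pairwise_agreement(cohort: pd.DataFrame, qtc_columns: list[str]) -> list[AgreementSummary]:
    """Agreement statistics for every unordered pair of corrected columns.

    Bland-Altman bias is the arithmetic mean of the differences; the
    limits of agreement are bias ± 1.96·SD (ddof=1).  When the
    differences have zero variance the paired-t p-value is NaN but the
    bias and limits are still reported.
    """
    if len(cohort) < 3:
        raise ValueError(f"pairwise agreement requires >= 3 rows, got {len(cohort)}")
    missing = [c for c in qtc_columns if c not in cohort.columns]
    if missing:
        raise ValueError(f"columns not found: {missing}")
    out = []
    for a, b in itertools.combinations(qtc_columns, 2):
        x = cohort[a].to_numpy(dtype=float)
        y = cohort[b].to_numpy(dtype=float)
        diff = x - y
        bias = float(diff.mean())
        sd = float(diff.std(ddof=1))
        if sd == 0:
            p = float("nan")
        else:
            p = float(scipy.stats.ttest_rel(x, y).pvalue)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            r = float("nan")
        else:
            r = float(scipy.stats.pearsonr(x, y).statistic)
        out.append(
            AgreementSummary(
                pair=(a.removeprefix("qtc_"), b.removeprefix("qtc_")),
                pearson_r=r,
                mean_difference=bias,
                paired_t_p=p,
                bias=bias,
                loa_low=bias - 1.96 * sd,
                loa_high=bias + 1.96 * sd,
            )
        )
    return out
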