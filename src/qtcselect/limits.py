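"""Reference limits of normal for corrected QT intervals.

The lower and upper limits of normal (LLN / ULN) are the 5th and 95th
empirical percentiles of the healthy subset, per formula and per sex.
Percentiles use the weighted-average definition at rank (n+1)·p — the
convention of the major commercial statistics packages — so results are
reproducible against them.  Confidence intervals are nonparametric
bootstrap percentile intervals (the CI method for empirical reference
limits is not standardised; the bootstrap is the package's declared
choice and is configurable by ``n_boot``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["NormalLimits", "compute_limits", "bootstrap_percentile_ci", "normal_limits_table"]

MIN_N = 20


@dataclass(frozen=True)
class NormalLimits:
    """Per-formula, per-sex reference limits in ms."""

    formula: str
    sex: str
    lln: float
    lln_ci: tuple[float, float]
    uln: float
    uln_ci: tuple[float, float]
    n_healthy: int

    def __post_init__(self) -> None:
        if self.lln > self.uln:
            raise ValueError(f"lln {self.lln} exceeds uln {self.uln}")


def _check_values(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1:
        raise ValueError("values must be one-dimensional")
    if len(values) < MIN_N:
        raise ValueError(f"need at least {MIN_N} values for interior percentiles, got {len(values)}")
    if not np.isfinite(values).all():
        raise ValueError("values must be finite")
    return values


def compute_limits(values, percentiles: tuple[float, float] = (5.0, 95.0)) -> tuple[float, float]:
    """Empirical (LLN, ULN) at the given percentiles, (n+1)·p weighted average."""
    values = _check_values(values)
    lo, hi = percentiles
    if not (0 < lo < hi < 100):
        raise ValueError(f"percentiles must satisfy 0 < lo < hi < 100, got {percentiles}")
    lln, uln = np.quantile(values, [lo / 100.0, hi / 100.0], method="weibull")
    return float(lln), float(uln)


def bootstrap_percentile_ci(
    values,
    percentile: float,
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bootstrap percentile CI for an empirical percentile.

    Resamples with replacement, recomputes the percentile of each
    resample, and takes the (1±level)/2 empirical quantiles of the
    bootstrap distribution.  Deterministic for a fixed ``seed``.
    """
    values = _check_values(values)
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    if not (0 < percentile < 100):
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    boot = np.quantile(values[idx], percentile / 100.0, method="weibull", axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def normal_limits_table(
    healthy: pd.DataFrame,
    qtc_columns: list[str],
    n_boot: int = 2000,
    seed: int = 0,
) -> list[NormalLimits]:
    """LLN/ULN with bootstrap CIs for each corrected column and sex.

    ``healthy`` must carry a ``male`` indicator and the corrected
    columns in ms.  Bootstrap seeds are derived deterministically from
    ``seed`` per (column, sex) cell.
    """
    out = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(2 * 2 * len(qtc_columns)) % (2**31))
    for col in qtc_columns:
        if col not in healthy.columns:
            raise ValueError(f"column {col!r} not found")
        for sex, flag in (("male", 1), ("female", 0)):
            vals = healthy.loc[healthy["male"] == flag, col].to_numpy(dtype=float)
            lln, uln = compute_limits(vals)
            lln_ci = bootstrap_percentile_ci(vals, 5.0, n_boot=n_boot, seed=int(next(seeds)))
            uln_ci = bootstrap_percentile_ci(vals, 95.0, n_boot=n_boot, seed=int(next(seeds)))
            out.append(
                NormalLimits(
                    formula=col.removeprefix("qtc_"),
                    sex=sex,
                    lln=lln,
                    lln_ci=lln_ci,
                    uln=uln,
                    uln_ci=uln_ci,
                    n_healthy=len(vals),
                )
            )
    return out
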