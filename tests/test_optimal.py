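"""Cohort-optimal correction fits: exact recovery, grid search, unbiasedness."""

import numpy as np
import pandas as pd
import pytest

from qtcselect import (
    GeneratorConfig,
    apply_custom_correction,
    fit_linear_hr,
    fit_linear_rr,
    fit_loglog_exponent,
    generate_cohort,
    grid_search_exponent,
)
from conftest import powerlaw_grid_cohort


def _linear_cohort(n=500, a=0.267, b=0.155, c=-0.009, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    rr = rng.uniform(0.5, 1.5, n)
    male = rng.integers(0, 2, n)
    qt = a + b * rr + c * male + (rng.normal(0, noise, n) if noise else 0.0)
    return pd.DataFrame({"male": male, "rr": rr, "hr": 60.0 / rr, "qt": qt})


def test_linear_rr_noise_free_recovery():
    """The generating coefficients QT = 0.267 + 0.155·RR − 0.009·male are recovered."""
    fit = fit_linear_rr(_linear_cohort())
    assert fit.intercept == pytest.approx(0.267, abs=1e-10)
    assert fit.slope == pytest.approx(0.155, abs=1e-10)
    assert fit.male_coeff == pytest.approx(-0.009, abs=1e-10)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-10)


def test_linear_rr_constant_qt_zero_slope():
    df = _linear_cohort(b=0.0, c=0.0)
    fit = fit_linear_rr(df, include_sex=False)
    assert fit.slope == pytest.approx(0.0, abs=1e-10)
    qtc, _ = apply_custom_correction(df, fit)
    np.testing.assert_allclose(qtc, 1000.0 * df["qt"], rtol=1e-12)


def test_linear_rr_too_few_rows_and_rank_deficiency():
    with pytest.raises(ValueError, match="at least 3"):
        fit_linear_rr(_linear_cohort(n=2))
    df = _linear_cohort(n=50)
    df["rr"] = 1.0
    with pytest.raises(ValueError, match="rank-deficient|constant"):
        fit_linear_rr(df, include_sex=False)


def test_linear_hr_exact_recovery_and_constant_error():
    df = _linear_cohort(n=200)
    df["qt"] = 0.5 - 0.0018 * df["hr"]
    fit = fit_linear_hr(df)
    assert fit.slope == pytest.approx(-0.0018, abs=1e-10)
    df["hr"] = 70.0
    with pytest.raises(ValueError, match="constant"):
        fit_linear_hr(df)


def test_linear_hr_slope_negative_on_power_law_cohort():
    """QT shortens as HR rises under the power-law generator."""
    c = generate_cohort(GeneratorConfig(n_subjects=4000, seed=3))
    assert fit_linear_hr(c).slope < 0


def test_loglog_recovers_female_exponent_0365():
    """Noise-free qt = c·rr^0.365 in the female stratum returns beta=0.365, SE≈0."""
    df = powerlaw_grid_cohort(0.365, n=500, male=0)
    fit = fit_loglog_exponent(df, "female")
    assert fit.beta == pytest.approx(0.365, abs=1e-12)
    assert fit.se_beta == pytest.approx(0.0, abs=1e-9)
    assert fit.r_squared == pytest.approx(1.0, abs=1e-12)


def test_loglog_zero_exponent_for_rate_independent_qt():
    df = powerlaw_grid_cohort(0.365, n=100, male=1)
    df["qt"] = 0.4
    assert fit_loglog_exponent(df, "male").beta == pytest.approx(0.0, abs=1e-12)


def test_loglog_slope_is_logarithm_base_invariant():
    """The fitted slope equals an independent base-10 polyfit oracle."""
    df = powerlaw_grid_cohort(0.413, n=300, male=1, noise_sd=0.005, seed=4)
    fit = fit_loglog_exponent(df, "male")
    oracle = np.polyfit(np.log10(df["rr"]), np.log10(df["qt"]), 1)[0]
    assert fit.beta == pytest.approx(oracle, abs=1e-10)


def test_loglog_rejects_bad_input():
    df = powerlaw_grid_cohort(0.333, n=50, male=1)
    with pytest.raises(ValueError, match="at least 3"):
        fit_loglog_exponent(df, "female")  # no female rows
    df.loc[0, "qt"] = -0.1
    with pytest.raises(ValueError, match="positive"):
        fit_loglog_exponent(df, "male")
    with pytest.raises(ValueError, match="sex"):
        fit_loglog_exponent(df, "other")


@pytest.mark.parametrize("exponent", [0.333, 0.413])
def test_grid_search_exact_on_noise_free_power_law(exponent):
    res = grid_search_exponent(powerlaw_grid_cohort(exponent, n=2000))
    assert res.d == exponent
    # at the matched exponent qtc is constant up to float64 rounding, so the
    # residual correlation is rounding noise, far below any off-grid value
    assert res.abs_corr_at_d < 1e-3
    off_grid = np.abs(res.correlations)[res.grid != exponent]
    assert res.abs_corr_at_d < off_grid.min() / 100


def test_grid_search_recovers_every_grid_exponent():
    """Exhaustive: each grid-aligned exponent is returned exactly on noise-free data."""
    grid = np.round(0.301 + 0.001 * np.arange(199), 3)
    rr = np.linspace(0.5, 1.5, 400)
    for e in grid:
        df = pd.DataFrame({"rr": rr, "qt": 0.4 * rr**e})
        assert grid_search_exponent(df).d == e


def test_grid_search_noisy_recovery_within_tolerance():
    df = powerlaw_grid_cohort(0.450, n=5000, noise_sd=0.008, seed=6)
    res = grid_search_exponent(df, d_max=0.599)
    assert res.d == pytest.approx(0.450, abs=0.010)


def test_grid_matches_loglog_within_one_step():
    df = powerlaw_grid_cohort(0.377, n=1000, male=1)
    d = grid_search_exponent(df).d
    beta = fit_loglog_exponent(df, "male").beta
    assert abs(d - beta) <= 0.001 + 1e-9


def test_grid_search_constant_rr_rejected():
    df = pd.DataFrame({"rr": np.ones(10), "qt": np.linspace(0.3, 0.5, 10)})
    with pytest.raises(ValueError, match="constant"):
        grid_search_exponent(df)


def test_grid_trace_min_is_reported_value():
    res = grid_search_exponent(powerlaw_grid_cohort(0.350, n=500))
    assert res.abs_corr_at_d == np.abs(res.correlations).min()
    assert len(res.grid) == 199


def test_ols_estimates_unbiased_over_replicates():
    """Mean coefficient error over 200 noisy replicates is < 2× the mean SE."""
    errors, ses = [], []
    for seed in range(200):
        fit = fit_linear_rr(_linear_cohort(n=300, seed=seed, noise=0.02))
        errors.append(fit.slope - 0.155)
        ses.append(fit.se_slope)
    assert abs(np.mean(errors)) < 2 * np.mean(ses) / np.sqrt(len(ses))


def test_apply_custom_correction_contracts():
    df = powerlaw_grid_cohort(0.333, n=1000, male=0)
    df.loc[len(df)] = {"subject_id": 0, "male": 1, "hr": 60.0, "rr": 1.0, "qt": 0.4}
    grid = grid_search_exponent(df.iloc[:-1])
    qtc, r2 = apply_custom_correction(df.iloc[:-1], grid)
    # the corrected column is constant up to float64 rounding; its regression
    # on rr explains only rounding noise
    assert r2 == pytest.approx(0.0, abs=1e-4)
    # rr = 1 rows are left unchanged by every method
    one = df.iloc[[-1]]
    for res in (grid, fit_linear_rr(df, include_sex=False), fit_linear_hr(df)):
        qtc_one, _ = apply_custom_correction(one, res)
        assert qtc_one.iloc[0] == pytest.approx(400.0, abs=1e-9)


def test_per_sex_exponents_required_and_complete():
    df = powerlaw_grid_cohort(0.333, n=40, male=0)
    df.loc[:19, "male"] = 1
    fit_m = fit_loglog_exponent(df, "male")
    with pytest.raises(ValueError, match="missing"):
        apply_custom_correction(df, {"male": fit_m})
    fit_f = fit_loglog_exponent(df, "female")
    qtc, _ = apply_custom_correction(df, {"male": fit_m, "female": fit_f})
    assert qtc.notna().all()
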