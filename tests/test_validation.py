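"""Prolongation flags, diagnostic metrics, Cox models, stepwise competition."""

import numpy as np
import pandas as pd
import pytest

from qtcselect import (
    NormalLimits,
    classify_prolonged,
    cox_fit,
    diagnostic_metrics,
    stepwise_competition,
)


def _limits(uln_male=450.0, uln_female=470.0, sexes=("male", "female")):
    out = {}
    if "male" in sexes:
        out["male"] = NormalLimits("bazett", "male", 380.0, (378, 382), uln_male,
                                   (448, 452), 100)
    if "female" in sexes:
        out["female"] = NormalLimits("bazett", "female", 395.0, (393, 397), uln_female,
                                     (468, 472), 100)
    return out


def brute_force_metrics(flags, deaths):
    """Independent row-by-row confusion-matrix count."""
    tp = fn = fp = tn = 0
    for f, d in zip(flags, deaths):
        if f and d:
            tp += 1
        elif not f and d:
            fn += 1
        elif f and not d:
            fp += 1
        else:
            tn += 1
    pct = lambda a, b: 100.0 * a / b if b else float("nan")
    return pct(tp, tp + fn), pct(tn, tn + fp), pct(tp, tp + fp), pct(tn, tn + fn)


def test_strict_inequality_at_the_limit():
    df = pd.DataFrame({"male": [1, 1, 0], "qtc_bazett": [450.0, 450.1, 470.0]})
    flags = classify_prolonged(df, "qtc_bazett", _limits())
    assert list(flags) == [0, 1, 0]


def test_sex_specific_limits_applied():
    df = pd.DataFrame({"male": [1, 0], "qtc_bazett": [460.0, 460.0]})
    flags = classify_prolonged(df, "qtc_bazett", _limits())
    assert list(flags) == [1, 0]  # above male ULN, below female ULN


def test_missing_sex_limit_rejected():
    df = pd.DataFrame({"male": [0, 0], "qtc_bazett": [400.0, 480.0]})
    with pytest.raises(ValueError, match="female"):
        classify_prolonged(df, "qtc_bazett", _limits(sexes=("male",)))


def test_confusion_matrix_hand_oracle():
    """TP=2 FN=8 FP=7 TN=83 gives sens 20.00, spec 92.22, ppv 22.22, npv 91.21."""
    flags = np.r_[np.ones(9), np.zeros(91)].astype(int)
    deaths = np.zeros(100, dtype=int)
    deaths[:2] = 1  # flagged deaths -> TP=2, FP=7
    deaths[9:17] = 1  # unflagged deaths -> FN=8, TN=83
    m = diagnostic_metrics(flags, deaths)
    assert (m.tp, m.fn, m.fp, m.tn) == (2, 8, 7, 83)
    assert m.sensitivity == pytest.approx(20.00, abs=0.005)
    assert m.specificity == pytest.approx(92.22, abs=0.005)
    assert m.ppv == pytest.approx(22.22, abs=0.005)
    assert m.npv == pytest.approx(91.21, abs=0.005)
    assert m.flagged_fraction == pytest.approx(9.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_metrics_equal_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    flags = rng.integers(0, 2, 500)
    deaths = rng.integers(0, 2, 500)
    m = diagnostic_metrics(flags, deaths)
    sens, spec, ppv, npv = brute_force_metrics(flags, deaths)
    assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (sens, spec, ppv, npv)


def test_metrics_invariant_under_dataset_duplication():
    rng = np.random.default_rng(10)
    flags = rng.integers(0, 2, 200)
    deaths = rng.integers(0, 2, 200)
    once = diagnostic_metrics(flags, deaths)
    twice = diagnostic_metrics(np.tile(flags, 2), np.tile(deaths, 2))
    assert (once.sensitivity, once.specificity, once.ppv, once.npv) == (
        twice.sensitivity, twice.specificity, twice.ppv, twice.npv
    )


def test_perfect_and_degenerate_classifiers():
    deaths = np.r_[np.ones(10), np.zeros(90)].astype(int)
    perfect = diagnostic_metrics(deaths, deaths)
    assert (perfect.sensitivity, perfect.specificity, perfect.ppv, perfect.npv) == (
        100.0, 100.0, 100.0, 100.0
    )
    none_flagged = diagnostic_metrics(np.zeros(100, dtype=int), deaths)
    assert none_flagged.sensitivity == 0.0
    assert np.isnan(none_flagged.ppv)  # 0/0 reported as missing, not zero
    assert none_flagged.npv == pytest.approx(90.0)
    with pytest.raises(ValueError, match="mismatch"):
        diagnostic_metrics(np.zeros(5), np.zeros(6))


def test_cox_recovers_known_log_hazard_ratio(exposed_survival_cohort):
    """ln(HR) estimate within 3 SE of ln 3 at n=20000, exposure prevalence 6.5%."""
    c = exposed_survival_cohort(20_000, 0.065, 3.0, seed=30)
    res = cox_fit(c, "exposed")
    log_hr = np.log(res.hazard_ratio)
    se = (np.log(res.ci_95[1]) - np.log(res.ci_95[0])) / (2 * 1.959964)
    assert abs(log_hr - np.log(3.0)) < 3 * se
    assert res.ci_95[0] <= res.hazard_ratio <= res.ci_95[1]
    assert res.n_events > 0


def test_cox_null_exposure_ci_covers_one(exposed_survival_cohort):
    """Under true HR=1 the 95% CI covers 1 at roughly the nominal rate."""
    hits = 0
    n_rep = 60
    for rep in range(n_rep):
        c = exposed_survival_cohort(2500, 0.3, 1.0, seed=100 + rep, baseline_hazard=5e-5)
        res = cox_fit(c, "exposed")
        hits += res.ci_95[0] <= 1.0 <= res.ci_95[1]
    # 3 SD band around binomial(n_rep, 0.95)
    assert hits >= n_rep * 0.95 - 3 * np.sqrt(n_rep * 0.95 * 0.05)


def test_cox_estimates_unbiased_over_replicates(exposed_survival_cohort):
    """Mean ln(HR) over replicates sits within 2 Monte-Carlo SEs of ln 3."""
    estimates = []
    for rep in range(60):
        c = exposed_survival_cohort(3000, 0.2, 3.0, seed=300 + rep, baseline_hazard=5e-5)
        estimates.append(np.log(cox_fit(c, "exposed").hazard_ratio))
    mc_se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
    assert abs(np.mean(estimates) - np.log(3.0)) < 2 * mc_se


def test_cox_zero_events_and_contracts(exposed_survival_cohort):
    c = exposed_survival_cohort(200, 0.1, 1.0, seed=31)
    c["death"] = 0
    c["cardiac_death"] = 0
    with pytest.raises(ValueError, match="no events"):
        cox_fit(c, "exposed")
    with pytest.raises(ValueError, match="missing columns"):
        cox_fit(c, "nonexistent")
    c2 = exposed_survival_cohort(200, 0.1, 1.0, seed=32)
    c2["exposed"] = 3
    with pytest.raises(ValueError, match="binary"):
        cox_fit(c2, "exposed")
    with pytest.raises(ValueError, match="outcome"):
        cox_fit(c2, "exposed", outcome="other")


def test_cardiac_outcome_censors_noncardiac_deaths(exposed_survival_cohort):
    c = exposed_survival_cohort(20_000, 0.065, 3.0, seed=33, baseline_hazard=5e-5)
    res = cox_fit(c, "exposed", outcome="cardiac")
    assert res.n_events == int(c["cardiac_death"].sum())
    assert res.n_events < int(c["death"].sum())


def test_stepwise_retains_truly_hazardous_flag(exposed_survival_cohort):
    """With one real flag (HR=3) and five null flags, the real one survives."""
    rng = np.random.default_rng(40)
    c = exposed_survival_cohort(8000, 0.065, 3.0, seed=41, baseline_hazard=5e-5)
    for j in range(5):
        c[f"null_{j}"] = (rng.random(len(c)) < 0.065).astype(int)
    res = stepwise_competition(c, ["exposed"] + [f"null_{j}" for j in range(5)])
    assert "exposed" in res.retained
    # forced covariates present in every step of the trace
    for step in res.trace:
        assert step["forced"] == ["age", "hr"]


def test_stepwise_all_null_flags_usually_empty(exposed_survival_cohort):
    """With only null flags, each flag survives at ~the removal threshold rate."""
    rng = np.random.default_rng(50)
    retained_total = 0
    n_rep = 20
    for rep in range(n_rep):
        c = exposed_survival_cohort(2500, 0.0, 1.0, seed=500 + rep, baseline_hazard=5e-5)
        for j in range(4):
            c[f"null_{j}"] = (rng.random(len(c)) < 0.1).astype(int)
        res = stepwise_competition(c, [f"null_{j}" for j in range(4)])
        retained_total += len(res.retained)
    # 4 flags x 20 reps at threshold 0.10: expect ~8 spurious retentions
    assert retained_total <= 25


def test_stepwise_drops_duplicate_columns(exposed_survival_cohort):
    c = exposed_survival_cohort(2000, 0.1, 2.0, seed=60, baseline_hazard=5e-5)
    c["copy"] = c["exposed"].copy()
    res = stepwise_competition(c, ["exposed", "copy"])
    assert res.dropped_duplicates == ("copy",)


def test_stepwise_trace_is_monotone_elimination(exposed_survival_cohort):
    c = exposed_survival_cohort(4000, 0.065, 3.0, seed=61, baseline_hazard=5e-5)
    rng = np.random.default_rng(62)
    for j in range(3):
        c[f"null_{j}"] = (rng.random(len(c)) < 0.065).astype(int)
    res = stepwise_competition(c, ["exposed", "null_0", "null_1", "null_2"])
    sizes = [len(s["flags_in_model"]) for s in res.trace]
    assert sizes == sorted(sizes, reverse=True)
    for first, second in zip(res.trace, res.trace[1:]):
        assert set(second["flags_in_model"]) <= set(first["flags_in_model"])
    # every retained flag is below the removal threshold in the final step
    final_p = res.trace[-1]["p_values"]
    assert all(final_p[f] < 0.10 for f in res.retained)
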