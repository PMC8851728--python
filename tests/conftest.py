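import numpy as np
import pandas as pd
import pytest

from qtcselect import (
    GeneratorConfig,
    SurvivalConfig,
    generate_cohort,
    generate_survival,
)


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """Default-condition cohort, n=7071, seed=1 (shared, read-only)."""
    return generate_cohort(GeneratorConfig(n_subjects=7071, seed=1))


@pytest.fixture(scope="session")
def healthy_default(default_cohort) -> pd.DataFrame:
    from qtcselect import apply_eligibility, correct_qt_batch, select_healthy

    eligible, _ = apply_eligibility(correct_qt_batch(default_cohort))
    healthy, _ = select_healthy(eligible)
    return healthy


def powerlaw_grid_cohort(exponent: float, n: int = 2000, scale: float = 0.4,
                         noise_sd: float = 0.0, seed: int = 0, male: int = 0) -> pd.DataFrame:
    """Noise-free (or noisy) power-law cohort over an even RR grid in [0.5, 1.5] s."""
    rr = np.linspace(0.5, 1.5, n)
    qt = scale * rr**exponent
    if noise_sd > 0:
        qt = qt + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return pd.DataFrame(
        {
            "subject_id": np.arange(1, n + 1),
            "male": np.full(n, male),
            "hr": 60.0 / rr,
            "rr": rr,
            "qt": qt,
        }
    )


@pytest.fixture
def exposed_survival_cohort():
    """Cohort with a known-hazard binary exposure attached, for Cox recovery."""

    def _make(n: int, exposure_prevalence: float, true_hr: float, seed: int,
              baseline_hazard: float | None = None) -> pd.DataFrame:
        rng = np.random.default_rng(seed)
        cohort = generate_cohort(GeneratorConfig(n_subjects=n, seed=seed))
        cohort["exposed"] = (rng.random(n) < exposure_prevalence).astype(int)
        kwargs = {} if baseline_hazard is None else {"baseline_hazard": baseline_hazard}
        return generate_survival(
            cohort,
            SurvivalConfig(exposure_column="exposed", true_hazard_ratio=true_hr,
                           seed=seed + 1, **kwargs),
        )

    return _make
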