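import numpy as np
import pytest

from arsmet.derived import add_derived_columns
from arsmet.imputation import impute_nondetects
from arsmet.model import ModelParameters, WATER_SOURCES
from arsmet.simulate import CohortConfig, generate_cohort_frame


def null_truth(alpha: float) -> ModelParameters:
    """Truth with no covariate or water effects: log10 level = alpha + noise."""
    return ModelParameters(
        alpha={s: alpha for s in WATER_SOURCES},
        beta={s: 0.0 for s in WATER_SOURCES},
        alpha_log_offset=1.0,
        beta_consumption=0.0,
        beta_creatinine=0.0,
        beta_female=0.0,
        beta_bmi=0.0,
        beta_age=0.0,
        beta_cotinine=0.0,
        beta_fish=0.0,
    )


@pytest.fixture(scope="session")
def default_config():
    return CohortConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-participant cohort under the default study conditions."""
    return generate_cohort_frame(CohortConfig(n_participants=300), seed=42)


@pytest.fixture(scope="session")
def imputed_small(small_cohort):
    return impute_nondetects(small_cohort, m=3, seed=7)


@pytest.fixture(scope="session")
def derived_small(imputed_small):
    return [add_derived_columns(ds.frame) for ds in imputed_small]


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
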