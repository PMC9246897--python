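import numpy as np
import pandas as pd
import pytest

from vigilant_ensemble.fusion import fuse
from vigilant_ensemble.pipeline import usable_covariates
from vigilant_ensemble.predictors import derive
from vigilant_ensemble.synthetic_data import CohortConfig, generate_cohort, generate_outcomes, simulate


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small end-to-end cohort: 4 participants, 40-day missions."""
    cfg = CohortConfig(n_participants=4, mission_days=40, seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_derived(tiny_cohort):
    fused = fuse(tiny_cohort.rst, tiny_cohort.env_streams)
    return derive(fused, tiny_cohort.demographics)


@pytest.fixture(scope="session")
def tiny_covariates(tiny_derived):
    return usable_covariates(tiny_derived)


@pytest.fixture(scope="session")
def clean_cohort():
    """Cohort with outcomes but no missingness (exact row counts)."""
    cfg = CohortConfig(n_participants=4, mission_days=40, seed=17)
    return generate_outcomes(generate_cohort(cfg))


class PerfectPredictor:
    """Stub: returns the observed outcome (oracle for zero-error paths)."""

    def __init__(self, outcome="lrm50"):
        self.outcome = outcome

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return df[self.outcome].to_numpy(dtype=float)


class ConstantPredictor:
    def __init__(self, value=0.0):
        self.value = value

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        return np.full(len(df), self.value)


@pytest.fixture
def perfect_fitter():
    return lambda train_df, seed: PerfectPredictor()


@pytest.fixture
def constant_fitter():
    return lambda train_df, seed: ConstantPredictor(0.0)
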