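"""Shared fixtures.

The expensive round-trip experiment (simulate a 21-subject cohort at the
published generative values, score it, fit the hierarchical tuning model at
the reduced MCMC setting) is session-scoped and shared between the recovery
tests and the correlation tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from oritune import observer, scoring
from oritune.tuning import MCMCConfig, fit_tuning_model

RECOVERY_SEED = 0  # canonical seed for the round-trip experiment


@pytest.fixture(scope="session")
def cohort_trials() -> pd.DataFrame:
    """21 simulated subjects at the default (published-mean) generative values."""
    return observer.simulate_cohort(n_subjects=21, seed=RECOVERY_SEED)


@pytest.fixture(scope="session")
def cohort_scored(cohort_trials):
    table, effects = scoring.score_trials(cohort_trials)
    return table, effects


@pytest.fixture(scope="session")
def cohort_fit(cohort_scored):
    """Reduced-MCMC hierarchical tuning fit of the simulated cohort."""
    _, effects = cohort_scored
    cfg = MCMCConfig(n_chains=4, n_iterations=1500, n_warmup=500, seed=RECOVERY_SEED)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_tuning_model(effects, mcmc=cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
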