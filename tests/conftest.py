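import numpy as np
import pytest
from hypothesis import settings

import circspline as cs
from circspline import models

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_cohort():
    """15 subjects from the default generating parameters."""
    profiles, truth = cs.simulate_cohort(cs.default_config(n_subjects=15), seed=101)
    return profiles, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """One REML fit of the unconstrained base model on the small cohort."""
    profiles, _ = small_cohort
    return models.fit_circadian(profiles, models.ModelSpec(constrained=False), seed=0)


@pytest.fixture(scope="session")
def constrained_fit(small_cohort):
    profiles, _ = small_cohort
    return models.fit_circadian(profiles, models.ModelSpec(constrained=True), seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
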