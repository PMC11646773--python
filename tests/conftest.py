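import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest simulated cohort shared by statistics tests."""
    from posturekit.synthio import CohortDesign, EffectSpec, simulate_cohort

    design = CohortDesign(n_per_group=(12, 9, 7), n_trials=4)
    return simulate_cohort(design, EffectSpec(), seed=17)


@pytest.fixture(scope="session")
def small_outcomes(small_cohort):
    from posturekit.synthio import outcomes_table

    return outcomes_table(small_cohort)
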