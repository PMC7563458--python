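import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small simulated cohort shared across integration tests.

    One 300-kb chromosome keeps the mapper stages fast while still
    exercising every pipeline stage (planting, anchored pairs, unique-hit
    filtering, windowing).
    """
    from tipscan.simulate import SimConfig, simulate_cohort

    config = SimConfig(
        seed=7,
        n_chroms=1,
        chrom_length=300_000,
        n_cases=2,
        n_controls=2,
        n_sites=4,
        coverage=10.0,
    )
    return simulate_cohort(config)
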