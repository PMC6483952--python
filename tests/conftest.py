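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


@pytest.fixture(scope="session")
def small_population():
    """A 300-animal, 20-block population reused across module tests."""
    from haploblup import SimulationConfig, simulate_population

    return simulate_population(
        SimulationConfig(
            n_animals=300,
            n_blocks=20,
            alleles_per_block=3,
            block_size_range=(2, 5),
            heritability=0.30,
            genetic_variance=1.0,
            seed=42,
        )
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
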