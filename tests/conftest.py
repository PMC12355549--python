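import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def strain_set():
    """A mid-sized strain panel reused by panel/io tests."""
    from paleokit.simulate import StrainSimConfig, simulate_strain_set

    return simulate_strain_set(
        StrainSimConfig(n_strains=6, genome_length=20_000, subs_per_branch=40, seed=101)
    )


@pytest.fixture(scope="session")
def noise_free_calls(strain_set):
    from paleokit.simulate import simulate_sample_calls

    return simulate_sample_calls(
        strain_set, coverage_mean=30.0,
        gq_model=lambda rng, n: np.full(n, 99, dtype=int), seed=202,
    )
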