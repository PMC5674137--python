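import hypothesis
import numpy as np
import pytest

from bulkseg.simulate import CrossSimConfig, simulate_cross

hypothesis.settings.register_profile(
    "fixed", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("fixed")


@pytest.fixture(scope="session")
def small_config():
    """A two-scaffold toy cross small enough for sub-second simulation."""
    return CrossSimConfig(
        n_scaffolds=2,
        scaffold_length=300_000,
        snp_density=0.002,
        qtl_scaffold=0,
        qtl_position=150_000,
        n_offspring=40,
        n_offspring_per_pool=(10, 10),
        mean_depth=30.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_cross(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
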