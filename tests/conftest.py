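import numpy as np
import pytest

from mwtriage import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default 20+20 cohort, shared read-only across tests."""
    return generate_cohort(SyntheticConfig(seed=1))


@pytest.fixture()
def tiny_config():
    """A small, fast cohort configuration (6+6 subjects, coarse grid)."""
    return SyntheticConfig(
        n_patients=6,
        n_controls=6,
        freq_start=0.1,
        freq_stop=1.9,
        freq_step=0.3,
        seed=7,
    )


@pytest.fixture()
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
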