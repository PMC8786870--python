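import numpy as np
import pytest

from depgrs.simulate import simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A modest simulated study shared by read-only tests."""
    return simulate_study(n_subjects=600, n_snps=24, seed=42,
                          discordant_fraction=0.25)


@pytest.fixture(scope="session")
def study_with_missing():
    return simulate_study(n_subjects=500, n_snps=12, seed=7,
                          missing_rate=0.02, underweight_rate=0.02)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
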