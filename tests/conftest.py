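import pytest

from cardiovar.cohort import load_bundled_registry
from cardiovar.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return load_bundled_registry()


@pytest.fixture(scope="session")
def small_cohort():
    """Compact seeded cohort reused by read-only tests."""
    return simulate_cohort(SimConfig(n_cases=40, n_controls=120, seed=11))
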