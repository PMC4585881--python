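import numpy as np
import pytest

from stomascale import StudyConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """The default nine-site synthetic study at seed 1 (shared, read-only)."""
    return simulate_study(StudyConfig(seed=1))


@pytest.fixture(scope="session")
def small_study():
    """A reduced study for fast I/O and CLI round-trips."""
    cfg = StudyConfig(seed=5, species_per_site=25)
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
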