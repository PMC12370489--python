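import numpy as np
import pytest

from swarmcast.panel import AsirPanel
from swarmcast.synthetic import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=42)


@pytest.fixture(scope="session")
def default_panel(default_config):
    """Full-shape panel: 32 years x (2 sexes x 12 ages)."""
    return generate_panel(default_config)


@pytest.fixture(scope="session")
def noiseless_config():
    return SyntheticConfig(noise_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_panel(noiseless_config):
    return generate_panel(noiseless_config)


@pytest.fixture(scope="session")
def small_config():
    """Cheap panel for training tests: 4 strata, 32 years."""
    return SyntheticConfig(
        age_groups=("40-44", "60-64"), noise_cv=0.0, seed=7
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return generate_panel(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_tiny_panel(values, start_year=2000, strata=None):
    """Helper for hand-built panels in unit tests."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    T, S = values.shape
    if strata is None:
        strata = tuple(("male", f"{40 + 5 * j}-{44 + 5 * j}") for j in range(S))
    years = tuple(range(start_year, start_year + T))
    return AsirPanel(years=years, strata=strata, values=values)
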