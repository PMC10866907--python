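import numpy as np
import pytest

from agipop.synthetic import ScenarioConfig, simulate_arrays


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition dataset, shared read-only across tests."""
    cfg = ScenarioConfig(seed=42, n_sites=1200, n_impact_sites=200, n_clinal_sites=60)
    return simulate_arrays(cfg)


@pytest.fixture(scope="session")
def rearing_dataset():
    """Rearing-history scenario: drifted bred/released pools, autozygous
    tracts, no release-impact sites or introgression."""
    cfg = ScenarioConfig(seed=7, n_sites=3000, n_impact_sites=0, n_clinal_sites=100,
                         introgression_m=0.0)
    return simulate_arrays(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
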