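import pytest

from promiscope.filters import FilterConfig
from promiscope.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def filter_config():
    """Shared filter configuration (PAINS catalogs are costly to build)."""
    return FilterConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """Default-scale noiseless planted dataset (8 series x 12 analogs)."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def conflicted_dataset():
    """Planted dataset with contradictory duplicate calls injected."""
    return generate_dataset(SyntheticSpec(seed=13, conflict_rate=0.1))
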