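import numpy as np
import pytest

from csifcm import ClusteringConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom_small():
    """Deterministic 96x96 modified phantom with 4-class ground truth."""
    return generate_phantom(96)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_config(**kwargs) -> ClusteringConfig:
    defaults = dict(tolerance=1e-5, max_iter=100, seed=0)
    defaults.update(kwargs)
    return ClusteringConfig(**defaults)
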