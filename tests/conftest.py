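import numpy as np
import pytest

from enfret.synthetic import SyntheticConfig, generate_ensemble


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig()


@pytest.fixture(scope="session")
def default_records(default_config):
    """The default 100-snapshot synthetic thermal ensemble."""
    return generate_ensemble(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240404)


def random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)
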