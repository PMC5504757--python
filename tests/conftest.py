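import numpy as np
import pytest

from pprlink import (
    CorruptionConfig,
    GeneratorConfig,
    corrupt_dataset,
    generate_master,
)

KEY = b"test-key"


@pytest.fixture(scope="session")
def secret_key() -> bytes:
    return KEY


@pytest.fixture(scope="session")
def master_small():
    """Small error-free master dataset with its truth mapping."""
    return generate_master(GeneratorConfig(n_records=400, seed=7))


@pytest.fixture(scope="session")
def corrupted_small(master_small):
    records, truth = master_small
    bad = corrupt_dataset(records, CorruptionConfig(error_rate=0.05, seed=8))
    return bad, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
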