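import numpy as np
import pytest

import pearhsi as p


@pytest.fixture(scope="session")
def default_table():
    """Full study-design synthetic table: 600 samples x 421 bands."""
    return p.generate_dataset()


@pytest.fixture(scope="session")
def small_table():
    """Compact table (5 stages x 12) for fast pipeline tests."""
    cfg = p.GeneratorConfig(n_per_stage=12, seed=7)
    return p.generate_dataset(cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
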