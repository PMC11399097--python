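import numpy as np
import pytest

from trwaxs.geometry import QGrid
from trwaxs.synthetic import GeneratorConfig, make_toy_structures, simulate_train_series


@pytest.fixture(scope="session")
def qgrid():
    return QGrid.linear(0.08, 1.5, 170)


@pytest.fixture(scope="session")
def toy_models():
    native, candidates = make_toy_structures(seed=1)
    return native, candidates


@pytest.fixture(scope="session")
def noiseless_series():
    """Small noiseless series: jitter and Poisson off, defaults otherwise."""
    cfg = GeneratorConfig(n_train_pairs=2, poisson=False, jitter_sd=0.0, seed=5)
    return cfg, simulate_train_series(cfg)


@pytest.fixture(scope="session")
def noisy_series():
    """Poisson + jitter series at generator defaults, reduced train count."""
    cfg = GeneratorConfig(n_train_pairs=20, seed=42)
    return cfg, simulate_train_series(cfg)
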