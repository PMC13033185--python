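import numpy as np
import pytest

from scdistill.io_preprocess import CountMatrix, preprocess
from scdistill.synthetic_data import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def tiny_counts() -> CountMatrix:
    """Small labelled 3-cluster dataset used across module tests."""
    cfg = SimConfig(n_cells=240, n_genes=180, n_marker_genes=30, seed=7)
    return simulate_counts(cfg)


@pytest.fixture(scope="session")
def tiny_processed(tiny_counts):
    return preprocess(tiny_counts, min_cells=3, n_top=150)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
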