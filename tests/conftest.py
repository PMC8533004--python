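import numpy as np
import pytest

from chromgraph.preprocess import GenomicBin
from chromgraph.synthetic import SyntheticScenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_bins():
    """Eight contiguous 25-kbp bins on a toy chromosome."""
    return [GenomicBin("chrT", i * 25_000, (i + 1) * 25_000, i) for i in range(8)]


@pytest.fixture
def small_scenario():
    """A scenario small enough for per-test pipeline runs."""
    return SyntheticScenario(
        n_bins=40, n_cells=80, n_edges=15, short_long_mix=0.25,
        dropout_rate=0.2, prior_fidelity=1.0, noise_edges=5, seed=7,
    )


def well_conditioned_cov(rng, p, n_factor=10, ridge=0.3):
    A = rng.normal(size=(n_factor * p, p))
    return A.T @ A / (n_factor * p) + ridge * np.eye(p)
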