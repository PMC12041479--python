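import numpy as np
import pytest

from mea_netpharm import SpikeTrainSet, SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_synth_cfg():
    """Scaled-down generator configuration for fast unit tests."""
    return SynthConfig(n_chips=4, n_electrodes=12, duration_s=180.0, seed=7)


@pytest.fixture
def tiny_sts():
    return SpikeTrainSet(
        chip_id="chipA",
        condition="pre_drug",
        duration_s=10.0,
        trains=[
            np.array([0.5, 1.5, 2.5, 9.0]),
            np.array([0.6, 1.4, 8.0]),
            np.array([]),
        ],
    )


def random_adjacency(rng, n, p):
    """Symmetric Erdos-Renyi adjacency with zero diagonal."""
    upper = rng.random((n, n)) < p
    A = np.triu(upper, 1)
    A = (A | A.T).astype(np.uint8)
    return A


@pytest.fixture
def er_graphs(rng):
    graphs = []
    for p in (0.2, 0.5, 0.8):
        for _ in range(17):
            n = int(rng.integers(4, 13))
            graphs.append(random_adjacency(rng, n, p))
    return graphs[:50]
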