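import numpy as np
import pytest

from tempopc import core, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def small_network():
    """5-node, 4-slice random nonnegative network."""
    return synthetic.generate_random_temporal_network(5, 4, density=0.8, seed=7)


@pytest.fixture
def signed_network(rng):
    """Symmetric zero-diagonal network with both signs of weight."""
    w = rng.normal(size=(6, 6, 3))
    w = (w + w.transpose(1, 0, 2)) / 2
    for t in range(3):
        np.fill_diagonal(w[:, :, t], 0.0)
    return core.TemporalNetwork(w)


@pytest.fixture
def recurring_ts():
    """Small recurring-state series (fast enough for unit tests)."""
    spec = synthetic.RecurringStateSpec(
        n_nodes=12, n_times=60, epoch_length=15, seed=5
    )
    return spec, synthetic.generate_recurring_timeseries(spec)
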