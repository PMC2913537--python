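import numpy as np
import pytest

import nsdbn as nd


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_continuous(rng):
    """2 nodes x 8 time points of standard-normal data."""
    return nd.TimeSeriesDataset(rng.standard_normal((2, 8)), ["X", "Y"])


@pytest.fixture
def small_discrete(rng):
    """2 binary nodes x 8 time points."""
    vals = rng.integers(1, 3, size=(2, 8))
    return nd.TimeSeriesDataset(vals, ["X", "Y"], mode="discrete",
                                n_categories=2)


@pytest.fixture
def sine_data():
    cfg = nd.SineNetworkConfig(seed=11)
    return nd.generate_sine_network(cfg)
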