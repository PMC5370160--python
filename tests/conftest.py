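import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from spikedeconv.synthetic import (ar1_benchmark_spec, ar2_benchmark_spec,
                                   simulate_batch, simulate_trace)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def ar1_traces():
    """Five benchmark AR(1) traces (gamma 0.95, sigma 0.3, T 3000)."""
    return simulate_batch(ar1_benchmark_spec(), 5, seed=101)


@pytest.fixture(scope="session")
def ar2_traces():
    """Three benchmark AR(2) traces (gamma (1.7, -0.712), sigma 1)."""
    return simulate_batch(ar2_benchmark_spec(), 3, seed=202)


@pytest.fixture(scope="session")
def short_ar1_trace():
    """A single short AR(1) trace for oracle-scale comparisons."""
    return simulate_trace(ar1_benchmark_spec(T=300), 7)
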