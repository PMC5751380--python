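import numpy as np
import pytest

import gaitjsrc as g


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The 20-subject, 9-class, 10-windows-per-class study cohort."""
    return g.simulate_gait_dataset(20, 9, 10, J=5, window_len=200, seed=11)


@pytest.fixture()
def small_dataset():
    """A small but non-trivial cohort for fast pipeline tests."""
    return g.simulate_gait_dataset(6, 3, 4, J=3, window_len=64, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
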