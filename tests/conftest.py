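import numpy as np
import pytest

from ecmoflow.pipeline import SweepConfig, run_sweep


@pytest.fixture(scope="session")
def default_sweep():
    """The default 4-level sweep; shared because it costs a couple seconds."""
    return run_sweep(SweepConfig())


@pytest.fixture
def grid_256():
    period = 0.8
    n = 256
    return np.arange(n) * period / n, period
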