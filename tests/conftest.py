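from dataclasses import replace

import pytest

from edsim.config import default_baseline


@pytest.fixture(scope="session")
def baseline():
    return default_baseline()


@pytest.fixture(scope="session")
def small():
    """Scaled-down world (half load, two days, five reps) for fast experiment tests."""
    return replace(default_baseline(), horizon=2880.0, arrival_scale=0.5, n_reps=5)
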