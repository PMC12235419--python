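import numpy as np
import pytest
from hypothesis import settings

from lucirhythm import table1

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table_report():
    """Full four-scenario analysis with default settings (computed once)."""
    return table1()


@pytest.fixture(scope="session")
def sample_grid():
    """Default 20-min sample grid over the standard 140-h horizon."""
    return np.arange(0.0, 140.0 + 1e-9, 1.0 / 3.0)
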