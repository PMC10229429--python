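import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/_oracles.py

from uihkit.core import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def uniform_trace():
    """100 s of 10-Hz samples with mild structure."""
    t = np.arange(0, 100, 0.1)
    v = 37.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t)
    return TimeSeries(t, v, "degC")
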