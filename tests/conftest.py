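import numpy as np
import pytest

from phasetrans import TimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def worked_example():
    """The 10-point step series whose CPA costs are known by hand."""
    return [2, 2, 2, 4, 4, 4, 4, 4, 4, 4]


def make_series(values, **kw) -> TimeSeries:
    return TimeSeries(np.asarray(values, dtype=float), **kw)
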