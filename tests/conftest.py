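import numpy as np
import pytest

from uncrflow.features import UNCRSeries


@pytest.fixture
def weekly_days():
    return np.arange(0, 140, 7.0)  # 20 weekly samples


@pytest.fixture
def flat_series(weekly_days):
    return UNCRSeries("flat", weekly_days, np.full(len(weekly_days), 133.0))


@pytest.fixture
def line_series(weekly_days):
    return UNCRSeries("line", weekly_days, 100.0 + 0.01 * weekly_days)


@pytest.fixture
def spiked_series(weekly_days):
    values = np.full(len(weekly_days), 100.0)
    values[7] = 500.0
    return UNCRSeries("spiked", weekly_days, values)
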