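import datetime as dt

import numpy as np
import pytest

from peakshift import PhenologyParams, TemperatureSeries

T0 = dt.date(2019, 11, 1)


@pytest.fixture
def params() -> PhenologyParams:
    return PhenologyParams()


@pytest.fixture
def const_series():
    def make(temp_c: float, n_days: int = 120, start: dt.date = T0) -> TemperatureSeries:
        return TemperatureSeries.constant(start, n_days, temp_c)

    return make


@pytest.fixture
def random_series():
    def make(seed: int, n_days: int = 150, lo: float = 5.0, hi: float = 25.0,
             start: dt.date = T0) -> TemperatureSeries:
        rng = np.random.default_rng(seed)
        return TemperatureSeries(start, rng.uniform(lo, hi, n_days))

    return make
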