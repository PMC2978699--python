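from datetime import datetime

import numpy as np
import pytest

from circatap import EquispacedSeries

START = datetime(2024, 1, 1, 0, 0, 0)


def make_series(values, step=600.0, start=START, label="test"):
    return EquispacedSeries(start, step, np.asarray(values, dtype=float), label)


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture
def hourly_week_pattern(rng):
    """A 7-day hourly series repeating one non-constant 24-h pattern."""
    day = rng.uniform(0, 1, 24)
    return make_series(np.tile(day, 7), step=3600.0)
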