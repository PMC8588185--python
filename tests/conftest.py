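import numpy as np
import pandas as pd
import pytest

from echocage.io import Echogram, EventSchedule


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_egram(values, r0=0.0, dr=1.0, t0=0.0, dt=1.0, **kw):
    values = np.asarray(values, dtype=float)
    kw.setdefault("transducer_depth", 24.0)
    return Echogram(
        ping_times=t0 + dt * np.arange(values.shape[0]),
        range_bins=r0 + dr * np.arange(values.shape[1]),
        values=values,
        **kw,
    )


def make_schedule(rows):
    return EventSchedule(pd.DataFrame(rows, columns=list(EventSchedule.COLUMNS)))


@pytest.fixture
def egram_factory():
    return make_egram


@pytest.fixture
def schedule_factory():
    return make_schedule
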