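import numpy as np
import pytest

import fearcode as fc


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_ts():
    """100-s flat-noise trace at 100 Hz with one event at t=50."""
    gen = np.random.default_rng(0)
    ts = fc.TimeSeries(gen.normal(0, 1, 10_000), sampling_rate=100.0)
    sched = fc.EventSchedule.from_events("CS_onset", [50.0], [30.0])
    return ts, sched


@pytest.fixture
def responder_session():
    """Small cell session with a strong 30% positive responder population."""
    cfg = fc.SynthConfig(seed=11, n_cells=40, fraction_positive=0.3,
                         effect_size=4.0)
    return fc.generate_cell_session(cfg)
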