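import numpy as np
import pytest

import divestates as ds


@pytest.fixture(scope="session")
def sim_cfg():
    return ds.default_sim_config(seed=0)


@pytest.fixture()
def dive_cfg():
    return ds.DiveConfig()


@pytest.fixture(scope="session")
def month_trace():
    """A 30-day labelled deployment rendered at 1 s, shared by round-trip tests."""
    cfg = ds.default_sim_config(seed=3)
    sim = ds.simulate_dive_sequence(cfg, 1200)
    dives = [d for d in sim if d.end_time < 30 * 86400]
    series = ds.render_depth_series(dives, 1.0)
    return dives, series


def make_series(times, depths, dt):
    return ds.DepthSeries(np.asarray(times, float), np.asarray(depths, float), dt)
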