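import numpy as np
import pandas as pd
import pytest

import birdyear as by
from birdyear import synthetic
from birdyear.io import RunConfig


@pytest.fixture(scope="session")
def sim_track():
    """Default-condition breeding track with ground truth (seed 42)."""
    cfg = by.SimConfig(seed=42)
    fixes, truth = by.simulate_track(cfg)
    return cfg, fixes, truth


@pytest.fixture(scope="session")
def breeding_bundle(sim_track):
    cfg, fixes, truth = sim_track
    rc = RunConfig(seed=42)
    return by.run_breeding(fixes, rc, stage="chick_rearing")


@pytest.fixture(scope="session")
def gls_year():
    """Scripted non-breeding year: truth, light and immersion streams (seed 7)."""
    cfg = by.SimConfig(seed=7)
    truth = synthetic.simulate_gls_year(cfg)
    light = synthetic.simulate_light(truth.daily_positions, cfg)
    activity = synthetic.simulate_activity(truth, cfg)
    return cfg, truth, light, activity


@pytest.fixture(scope="session")
def nonbreeding_bundle(gls_year):
    cfg, truth, light, activity = gls_year
    rc = RunConfig(seed=7)
    span = (pd.Timestamp("2020-01-10T00:00Z"), pd.Timestamp("2020-01-19T23:59Z"))
    return by.run_nonbreeding(light, activity, rc, calibration_span=span)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
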