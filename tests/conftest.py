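"""Shared fixtures: synthetic records generated once per session."""

import numpy as np
import pandas as pd
import pytest

from hydrurga import simulate

BIRD_ISLAND = (-38.05, -54.01)


@pytest.fixture(scope="session")
def stationary_lights():
    """30-day noiseless light record for a logger fixed at the deployment site."""
    track = simulate.stationary_track(BIRD_ISLAND, "2013-05-01", 30)
    return simulate.render_light(track, zenith_deg=96.0, threshold=10.0, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_track():
    """Short residency track at the deployment site."""
    params = simulate.TrackParams(n_steps=60, seed=7, start_time="2013-05-01")
    track, truth = simulate.simulate_track(params)
    return track


@pytest.fixture(scope="session")
def env_grids():
    return simulate.simulate_environment(simulate.EnvFieldSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
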