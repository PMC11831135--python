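import numpy as np
import pandas as pd
import pytest

from coalcrop.model import CoalAttributionModel
from coalcrop.synth import WorldConfig, generate_world


@pytest.fixture(scope="session")
def small_world():
    """A compact world with noise, used by most downstream tests."""
    cfg = WorldConfig(
        seed=42,
        n_points=500,
        n_stations=6,
        n_states=3,
        years=(2019, 2020, 2021),
        station_cluster_frac=0.7,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def small_results(small_world):
    model = CoalAttributionModel.from_world(small_world)
    return model.fit()


@pytest.fixture(scope="session")
def noiseless_world():
    """All random components zeroed and stations far apart, so the observed
    NO2 is exactly the directional exposure linear predictor and every
    point sees at most one station."""
    cfg = WorldConfig(
        seed=2,
        n_points=500,
        n_stations=5,
        n_states=2,
        years=(2019, 2020, 2021),
        fe_sd_point=0.0,
        fe_sd_state_season=0.0,
        noise_sd=0.0,
        weather_betas=(0.0, 0.0),
        no2_baseline=0.0,
        min_station_separation_km=205.0,
        station_cluster_frac=0.8,
    )
    return generate_world(cfg)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_world):
    return CoalAttributionModel.from_world(noiseless_world).fit()


def rand_latlon(rng, n):
    lat = rng.uniform(-60, 60, n)
    lon = rng.uniform(-179, 179, n)
    return lat, lon
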