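import numpy as np
import pandas as pd
import pytest

from stdelta import ModelConfig, SimScenario, fit, simulate_survey
from stdelta.geo import validate_stations


@pytest.fixture(scope="session")
def small_sim():
    """Desk-scale simulated survey shared across tests (4 years, 10 knots)."""
    scenario = SimScenario(n_years=4, stations_per_year=60, n_knots=10, seed=3)
    return simulate_survey(scenario)


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """Correctly specified fit of the small simulation (no SE Hessian)."""
    cfg = ModelConfig(n_knots=10, fields_on=("omega1", "eps1"), range_km=150.0,
                      seed=3, compute_se=False)
    return fit(small_sim.stations, cfg, mesh=small_sim.mesh)


def km_table(xy, year=2000, **cols):
    """Station table from km coordinates (inverse of the plate projection)."""
    xy = np.asarray(xy, dtype=float)
    lat = xy[:, 1] / 111.195
    lon = xy[:, 0] / (111.195 * np.cos(np.deg2rad(lat))) - 180.0
    df = pd.DataFrame({
        "station_id": [f"s{i}" for i in range(len(xy))],
        "year": year, "lon": lon, "lat": lat,
        "area_swept": 0.2, "catch": 1.0,
    })
    for k, v in cols.items():
        df[k] = v
    return validate_stations(df)


def toy_stations(n, seed=0, n_years=1, enc=0.7, lat0=55.0, spread=0.001):
    """Small synthetic station table with iid gamma catches (no spatial truth)."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_years):
        for i in range(n):
            c = rng.gamma(2.0, 2.0) if rng.random() < enc else 0.0
            rows.append(dict(
                station_id=f"s{t}_{i}", year=2000 + t,
                lon=-170.0 + i * spread, lat=lat0 + t * 0.01,
                area_swept=0.2, catch=c,
            ))
    return validate_stations(pd.DataFrame(rows))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
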