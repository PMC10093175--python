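import numpy as np
import pandas as pd
import pytest

from swimtrack import synthetic


@pytest.fixture(scope="session")
def uniform_field():
    """Uniform eastward 0.3 m/s current field, 8 days."""
    spec = synthetic.CurrentFieldSpec(kind="uniform", u0=0.3, v0=0.0, days=8,
                                      resolution_deg=0.25)
    return synthetic.build_field(spec, seed=42)


@pytest.fixture(scope="session")
def vortex_field():
    spec = synthetic.CurrentFieldSpec(kind="vortex", vortex_center=(-81.0, 19.5),
                                      vortex_peak_ms=0.5, vortex_radius_km=100.0,
                                      days=8, resolution_deg=0.25)
    return synthetic.build_field(spec, seed=43)


@pytest.fixture(scope="session")
def small_cohort():
    """Six dispersive January-like animals (no residents), 10 days."""
    return synthetic.make_cohort("jan", 6, seed=7, n_residential=0,
                                 duration_days=10.0)


@pytest.fixture()
def straight_decomp():
    """Hand-built decomposition: due-north 10 km/day corrected track."""
    n = 8
    lat = 19.0 + np.arange(n) * 10.0 / 111.19492664455873
    return pd.DataFrame({
        "animal_id": "t1",
        "date": pd.date_range("2022-01-22", periods=n, freq="D"),
        "lon": -81.0, "lat": lat,
        "corr_lon": np.full(n, -81.0), "corr_lat": lat,
        "ground_east": 0.0, "ground_north": 10.0,
        "cur_east": 0.0, "cur_north": 0.0,
        "swim_east": np.r_[np.zeros(n - 1), np.nan],
        "swim_north": np.r_[np.full(n - 1, 10.0), np.nan],
        "swim_speed": 10.0, "cur_speed": 0.0,
    })
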