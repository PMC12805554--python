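import numpy as np
import pandas as pd
import pytest

from spatialproxy import (RegionTable, make_grid_cities, scenario_preset,
                          simulate)


@pytest.fixture(scope="session")
def base_config():
    return scenario_preset("base")


@pytest.fixture(scope="session")
def grid10_geometry():
    return make_grid_cities(10, 7)


@pytest.fixture(scope="session")
def base_dataset(base_config, grid10_geometry):
    """One base-case simulated dataset (490 regions, 10 cities)."""
    return simulate(base_config, grid10_geometry, seed=1234)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset: 2 cities of 5x5 regions."""
    cfg = scenario_preset("base").replace(n_cities=2, grid_dim=5)
    return simulate(cfg, make_grid_cities(2, 5), seed=99)


@pytest.fixture()
def tiny_table():
    """20-region single-city table with no geometry (for r=0 fits)."""
    rng = np.random.default_rng(7)
    n = 20
    df = pd.DataFrame({
        "city": 1, "region": np.arange(1, n + 1),
        "outcome": rng.normal(size=n),
        "treatment": rng.integers(0, 2, size=n),
        "w1": rng.normal(size=n),
    })
    return RegionTable(df=df)
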