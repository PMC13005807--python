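import numpy as np
import pandas as pd
import pytest

from gridepi import synthetic as syn


@pytest.fixture(scope="session")
def small_config() -> syn.ScenarioConfig:
    return syn.ScenarioConfig(
        grid_nx=12,
        grid_ny=12,
        background_pop_mean=150.0,
        n_units=9,
        urban_fraction=0.25,
        relocation_prob=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_grid(small_config) -> pd.DataFrame:
    return syn.generate_grid(small_config)


@pytest.fixture(scope="session")
def small_cases(small_config, small_grid):
    return syn.generate_case_histories(small_grid, small_config)


def make_grid(x, y, population, cell_size=1000.0):
    """Hand-built grid table for targeted geometry tests."""
    x = np.asarray(x, dtype=float)
    return pd.DataFrame(
        {
            "cell_id": np.arange(len(x)),
            "x": x,
            "y": np.asarray(y, dtype=float),
            "population": np.asarray(population, dtype=np.int64),
            "unit_id": np.zeros(len(x), dtype=np.int64),
        }
    )
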