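import numpy as np
import pandas as pd
import pytest
import xarray as xr

from heatcase.synthetic import CascadeNoise, SimulationConfig, simulate_study
from heatcase.linkage import apply_exclusions, link_records
from heatcase.design import build_strata

#: the defect counts used throughout the exclusion-cascade tests
NOISE = CascadeNoise(
    n_duplicates=5, n_outside_extent=2, n_non_summer=10, n_under_age=3,
    n_missing=1,
)


def run_chain(config: SimulationConfig, seed: int = 0):
    """simulate -> exclude -> link -> strata, returning every intermediate."""
    study = simulate_study(config)
    retained, report = apply_exclusions(study.records, study.temperature)
    linked = link_records(
        retained, study.temperature, study.covariates, study.holidays,
        lag_set=config.lag_set, seed=seed,
    )
    strata = build_strata(
        linked, study.temperature, study.covariates, study.holidays,
        lag_set=config.lag_set,
    )
    return study, retained, report, linked, strata


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=5, expected_events=800, noise=NOISE)


@pytest.fixture(scope="session")
def small_chain(small_config):
    return run_chain(small_config, seed=5)


@pytest.fixture(scope="session")
def medium_chain():
    """~3000 events, clean (no injected defects): inference-grade dataset."""
    return run_chain(SimulationConfig(seed=1, expected_events=3000), seed=1)


def toy_surface(tmean_by_date: dict, shape=(2, 2)) -> xr.Dataset:
    """Single-valued daily field on a tiny grid, for hand-computed checks."""
    times = pd.DatetimeIndex(sorted(tmean_by_date))
    ny, nx = shape
    vals = np.array([np.full(shape, float(tmean_by_date[t])) for t in times])
    return xr.Dataset(
        {
            "tmin": (("time", "y", "x"), vals.copy()),
            "tmax": (("time", "y", "x"), vals.copy()),
            "region": (("y", "x"), np.zeros(shape, dtype=np.int32)),
        },
        coords={
            "time": times,
            "y": (np.arange(ny) + 0.5),
            "x": (np.arange(nx) + 0.5),
        },
        attrs={
            "cell_size": 1.0,
            "coarse_factor": 1,
            "extent_x": float(nx),
            "extent_y": float(ny),
        },
    )
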