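"""Shared fixtures: small deterministic datasets built in memory."""

import math

import numpy as np
import pandas as pd
import pytest

import paleodrivers as pdv
from paleodrivers.containers import PredictorSeries
from paleodrivers.simulate import SimulationTruth


@pytest.fixture
def three_species():
    return pdv.LifespanTable(pd.DataFrame({
        "species_id": ["a", "b", "c"],
        "ts": [10.0, 8.0, 60.0],
        "te": [5.0, 0.0, 58.0],
    }))


@pytest.fixture
def ou_predictors():
    """Three standardized OU predictor series on [0, 100] Ma."""
    series = []
    for j in range(3):
        raw = pdv.simulate_predictor_series(
            pdv.PredictorTruth(kind="ou", reversion=0.05),
            100.0, seed=100 + j, name=f"x{j + 1}",
        )
        series.append(pdv.standardize_series(
            raw.ages, raw.raw, 100.0, name=raw.name, log_transform=False
        ))
    return series


@pytest.fixture(scope="session")
def constant_rate_table():
    """~350 species simulated at constant lambda=0.15, mu=0.05."""
    truth = SimulationTruth(
        lambda0=0.15, mu0=0.05, t_start=30.0, n_founders=10, seed=3
    )
    return pdv.simulate_bd_lifespans(truth)


def step_shift_dataset(seed: int = 9):
    """Lifespans whose speciation rate is 0.05 younger than 50 Ma and
    0.3 older, with constant extinction 0.25 (window [0, 70))."""
    ages = np.round(np.arange(0, 70.05, 0.1), 9)
    x = np.where(ages >= 50.0, 1.0, -1.0)
    x = (x - x.mean()) / x.std()
    step = PredictorSeries("step", ages, x, transformed=x)
    xy, xo = x.min(), x.max()
    g = math.log(0.3 / 0.05) / (xo - xy)
    lam0 = 0.05 * math.exp(-g * xy)
    truth = SimulationTruth(
        lambda0=lam0, mu0=0.25, g_lambda=(g,), g_mu=(0.0,),
        t_start=70.0, n_founders=50, seed=seed,
    )
    return pdv.simulate_bd_lifespans(truth, [step]), step


@pytest.fixture
def square_grid():
    """40x40 all-land flat square at 100 m, cellsize 1 km."""
    elev = np.full((40, 40), 100.0)
    return pdv.ElevationGrid(
        elevation=elev, mask=np.ones((40, 40), bool), cellsize=1.0
    )
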