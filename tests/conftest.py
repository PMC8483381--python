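"""Shared fixtures: small synthetic populations and simple hand-built tracks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from fptnsd.simulate import SyntheticConfig, generate_population
from fptnsd.telemetry import CaribouYear, Trajectory, _make_year

TZ = "America/Anchorage"


def make_track(xy_km, start="2004-07-01 00:00", interval_h=12.0,
               animal_id="A", tz=TZ) -> Trajectory:
    """Trajectory from planar waypoints (km), evenly spaced in time."""
    xy = np.asarray(xy_km, dtype=float) * 1000.0
    n = len(xy)
    t = pd.date_range(pd.Timestamp(start, tz=tz),
                      periods=n, freq=pd.Timedelta(hours=interval_h))
    df = pd.DataFrame({"t": t, "lon": np.zeros(n), "lat": np.zeros(n),
                       "x": xy[:, 0], "y": xy[:, 1]})
    return Trajectory(animal_id=animal_id, df=df, crs="planar-test")


def make_year(xy_km, start="2004-07-01 00:00", interval_h=12.0,
              animal_id="A", tz=TZ) -> CaribouYear:
    """CaribouYear from planar waypoints (km), evenly spaced in time."""
    traj = make_track(xy_km, start, interval_h, animal_id, tz)
    ys = pd.Timestamp(2004, 7, 1, tz=tz)
    return _make_year(animal_id, ys, traj.df, interval_h=interval_h)


@pytest.fixture(scope="session")
def small_population():
    """~60 synthetic caribou-years at a 12-h schedule with ground truth."""
    cfg = SyntheticConfig(seed=11, n_individuals=28, fix_mix={12: 1.0})
    years, truths = generate_population(cfg)
    return cfg, years, truths


@pytest.fixture(scope="session")
def migrant_year(small_population):
    """One clean full-duration migrant year and its truth record."""
    _, years, truths = small_population
    for cy, t in zip(years, truths):
        if t.true_class == "migrant" and cy.duration_days > 360:
            return cy, t
    raise RuntimeError("fixture population contains no full migrant year")
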