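"""Shared fixtures: small synthetic worlds and the bundled study fixture
(100 vessels, 90 days, seed 0) used by the end-to-end checks."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

import darkgaps as dg

FIXTURE_SEED = 0
FIXTURE_VESSELS = 100
FIXTURE_DAYS = 90


def make_messages(times_h, lons=None, lats=None, vessel_id="900000001",
                  device_class="A", gear="trawler", flag="CHN"):
    """Hand-built message table from hour offsets (single vessel)."""
    times_h = np.asarray(times_h, dtype=float)
    n = len(times_h)
    lons = np.full(n, -35.1) if lons is None else np.asarray(lons, dtype=float)
    lats = np.full(n, -25.1) if lats is None else np.asarray(lats, dtype=float)
    return pd.DataFrame({
        "vessel_id": vessel_id,
        "timestamp": (pd.Timestamp("2018-01-01", tz="UTC")
                      + pd.to_timedelta(times_h, unit="h")).floor("s"),
        "lon": lons, "lat": lats, "device_class": device_class,
        "is_fishing": True, "gear": gear, "flag": flag})


@pytest.fixture(scope="session")
def small_world():
    """10x10 degree world, 40x40 quarter-degree cells."""
    return dg.build_world(dg.WorldConfig(west=-40, south=-30, east=-30,
                                         north=-20, seed=3))


@pytest.fixture(scope="session")
def study_fixture():
    """The bundled study conditions: 100 vessels x 90 days at seed 0, with
    reception maps, filtered+labelled gaps, and the selected rule model."""
    world = dg.build_world(dg.WorldConfig(seed=FIXTURE_SEED))
    fleet = dataclasses.replace(dg.FleetConfig(seed=FIXTURE_SEED),
                                n_vessels=FIXTURE_VESSELS)
    messages, truth = dg.simulate_fleet(world, fleet, FIXTURE_DAYS)
    observed = dg.observed_reception(messages, 1.0)
    predicted = {d: dg.predict_reception(g, 0.25) for d, g in observed.items()}
    gaps = dg.detect_gaps(messages)
    gaps = dg.filter_gaps(gaps, world.shore_distance_km, predicted)
    gaps = dg.label_gaps(gaps, truth)
    return {"world": world, "messages": messages, "truth": truth,
            "observed": observed, "predicted": predicted, "gaps": gaps}
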