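"""Shared fixtures: hand-built planar tracks and simulated bat-nights."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from fptseg.projection import TransverseMercator
from fptseg.simulate import (PatchSpec, SimConfig, random_night_config,
                             sample_gps, simulate_night, truth_at_slots)
from fptseg.trackio import Roost, Track, filter_track, project

TM = TransverseMercator(zone=14, north=True)
ROOST_LONLAT = (-98.60, 20.45)
ROOST_XY = tuple(float(v) for v in TM.forward(*ROOST_LONLAT))


def planar_track(x, y, t_seconds, individual="t1",
                 t0="2022-05-16T02:30:00Z") -> Track:
    """A projected Track from planar offsets (m) relative to the roost."""
    x = np.asarray(x, dtype=float) + ROOST_XY[0]
    y = np.asarray(y, dtype=float) + ROOST_XY[1]
    lon, lat = TM.inverse(x, y)
    ts = pd.Timestamp(t0) + pd.to_timedelta(np.asarray(t_seconds, dtype=float), unit="s")
    fixes = pd.DataFrame({"timestamp": ts, "lon": lon, "lat": lat,
                          "valid": True, "x": x, "y": y})
    return Track(individual_id=individual, fixes=fixes, crs=TM)


def straight_track(speed=7.0, interval_s=600.0, n=12, heading=90.0) -> Track:
    """Constant-speed straight line heading north by default."""
    t = np.arange(n) * interval_s
    d = speed * t
    th = math.radians(heading)
    return planar_track(d * math.cos(th), d * math.sin(th), t)


def random_walk_track(rng, n=40, step_scale=2000.0, interval_s=600.0) -> Track:
    """An irregular synthetic test path (not a behavioural simulation)."""
    steps = rng.normal(0.0, step_scale, (n - 1, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    return planar_track(xy[:, 0], xy[:, 1], np.arange(n) * interval_s)


def night_to_track(night, config=None) -> tuple[Track, pd.Series]:
    """sample_gps -> filter -> project, plus slot-aligned truth states."""
    config = config or night.config
    gps = sample_gps(night, config)
    fixes = pd.DataFrame({
        "timestamp": gps["timestamp"],
        "lon": gps["location-long"],
        "lat": gps["location-lat"],
        "valid": (gps["fix-status"] == "valid").to_numpy(),
    })
    track = Track(individual_id=config.individual_id, fixes=fixes,
                  fix_interval=config.fix_interval)
    track = filter_track(track, roost=Roost(*config.roost_lonlat))
    track = project(track, TransverseMercator.for_point(*config.roost_lonlat))
    truth = truth_at_slots(night, config).set_index("timestamp")["state"]
    return track, truth


def single_patch_config(seed, radius=400.0, distance=20000.0, bearing_deg=90.0,
                        **overrides) -> SimConfig:
    th = math.radians(bearing_deg)
    patch = PatchSpec(center=(distance * math.cos(th), distance * math.sin(th)),
                      radius=radius, habitat="shrubland")
    kw = dict(patches=(patch,), trip_itineraries=((0,),), seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


@pytest.fixture(scope="session")
def default_night():
    """One representative simulated night (2 trips, dropout 0.3)."""
    rng = np.random.default_rng(42)
    cfg = random_night_config(rng, dropout_prob=0.3, n_trips=2)
    return simulate_night(cfg), cfg


@pytest.fixture(scope="session")
def processed_night(default_night):
    night, cfg = default_night
    track, truth = night_to_track(night, cfg)
    return night, cfg, track, truth


@pytest.fixture(scope="session")
def projected_roost():
    return Roost(*ROOST_LONLAT).projected(TM)
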