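"""Synthetic central-place-forager nights with known behavioural states.

The generator emulates one-night GPS deployments on lactating
nectar-feeding bats commuting from a maternity roost to nectar patches:

* a two-mode composite correlated random walk at 1-s resolution —
  fast, target-directed commuting (~7 m/s) versus slow, tortuous
  area-restricted search inside circular patches of 300–500 m radius
  placed 13–40 km from the roost;
* 1–3 roost-to-roost round trips per night separated by 30–90 min
  roost dwells (the tag records nothing inside the roost, which is what
  produces the characteristic inter-trip gaps in real data);
* a GPS duty-cycle model: fixes every 10 or 15 min across the night,
  each failing independently with a configurable probability (~47% in
  the emulated field campaign), and isotropic Gaussian position error.

Everything is seeded and bit-reproducible, and the continuous 1-s path
doubles as the brute-force substrate for first-passage-time oracles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .projection import TransverseMercator

HABITATS = ("shrubland", "forest", "farmland")
LANDCOVER_CODES = {"background": 0, "shrubland": 1, "forest": 2, "farmland": 3}
CODE_TO_HABITAT = {v: k for k, v in LANDCOVER_CODES.items()}

# ground-truth state codes
ROOST, COMMUTE, FORAGE = 0, 1, 2
STATE_NAMES = {ROOST: "ROOST", COMMUTE: "COMMUTE", FORAGE: "FORAGE"}

_MIN_SPEED = 0.1          # m/s floor; slower draws are rejected and redrawn
_BOUT_FLOOR = 600.0       # s; a patch visit shorter than this is not worth simulating
_COMMUTE_SLACK = 1.15     # planning factor over straight-line commute time


@dataclass(frozen=True)
class PatchSpec:
    """A circular nectar patch: centre (m, roost-origin frame), radius, habitat."""

    center: tuple[float, float]
    radius: float
    habitat: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("patch radius must be positive")
        if self.habitat not in HABITATS:
            raise ValueError(f"habitat must be one of {HABITATS}, got {self.habitat!r}")

    @property
    def distance(self) -> float:
        return math.hypot(*self.center)


@dataclass(frozen=True)
class SimConfig:
    """One simulated bat-night.

    The planar frame has the roost at the origin; ``roost_lonlat`` anchors
    it geographically so tracks can be exported as WGS84 Movebank CSV.
    ``trip_itineraries`` gives, per trip, the indices of the patches
    visited in order.
    """

    patches: tuple[PatchSpec, ...]
    trip_itineraries: tuple[tuple[int, ...], ...] = ((0,),)
    roost_lonlat: tuple[float, float] = (-98.60, 20.45)
    date: str = "2022-05-15"            # local calendar date of dusk
    night_start: str = "20:30"          # local clock
    night_end: str = "05:30"
    utc_offset_hours: float = -6.0
    fix_interval: float = 10.0          # minutes
    commute_speed_mean: float = 7.0     # m/s
    commute_speed_sd: float = 1.0
    forage_speed_mean: float = 1.5
    forage_speed_sd: float = 0.5
    commute_heading_sd: float = 0.10    # rad per 1-s step around the target bearing
    forage_heading_sd: float = 0.20     # rad per 1-s step (smoothly curving search)
    forage_core_frac: float = 0.30      # stationary within-patch position sd / patch radius
    roost_dwell_range: tuple[float, float] = (30.0, 90.0)   # minutes
    bout_range: tuple[float, float] = (60.0, 150.0)         # minutes per patch visit
    dropout_prob: float = 0.47
    position_error_sd: float = 15.0     # m
    individual_id: str = "2201"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patches:
            raise ValueError("at least one patch is required")
        if self.commute_speed_mean <= self.forage_speed_mean:
            raise ValueError("commute speed must exceed forage speed")
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must be in [0, 1)")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be positive")
        for trip in self.trip_itineraries:
            for idx in trip:
                if not 0 <= idx < len(self.patches):
                    raise ValueError(f"itinerary references unknown patch {idx}")

    @property
    def n_trips(self) -> int:
        return len(self.trip_itineraries)

    @property
    def night_seconds(self) -> int:
        t0 = _clock_seconds(self.night_start)
        t1 = _clock_seconds(self.night_end)
        return int((t1 - t0) % 86400)

    def night_start_utc(self) -> pd.Timestamp:
        local = pd.Timestamp(f"{self.date} {self.night_start}")
        return (local - pd.Timedelta(hours=self.utc_offset_hours)).tz_localize("UTC")


def _clock_seconds(hhmm: str) -> int:
    h, m = hhmm.split(":")
    return int(h) * 3600 + int(m) * 60


@dataclass
class GroundTruth:
    """Per-second behavioural truth aligned with the continuous path."""

    state: np.ndarray       # int8, ROOST/COMMUTE/FORAGE
    trip: np.ndarray        # int16, 1-based; 0 while in the roost
    patch: np.ndarray       # int16, patch index; -1 when not foraging

    def state_names(self) -> np.ndarray:
        return np.vectorize(STATE_NAMES.get)(self.state)

    def to_frame(self, night_start_utc: pd.Timestamp) -> pd.DataFrame:
        t = night_start_utc + pd.to_timedelta(np.arange(self.state.size), unit="s")
        return pd.DataFrame({"timestamp": t, "state": self.state_names(),
                             "trip": self.trip, "patch": self.patch})


@dataclass
class SimulatedNight:
    """Continuous 1-s path plus ground truth for one config/seed."""

    config: SimConfig
    t: np.ndarray           # seconds since night start, 0..T inclusive
    x: np.ndarray           # m, roost at origin
    y: np.ndarray
    truth: GroundTruth

    @property
    def n_steps(self) -> int:
        return self.t.size

    def position_at(self, seconds) -> tuple[np.ndarray, np.ndarray]:
        """Linear interpolation (the path is 1 Hz, so this is essentially exact)."""
        s = np.asarray(seconds, dtype=float)
        return np.interp(s, self.t, self.x), np.interp(s, self.t, self.y)


class UnreachablePatchError(RuntimeError):
    pass


def _draw_speeds(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Normal speed draws, rejecting anything below the 0.1 m/s floor."""
    out = rng.normal(mean, sd, n)
    bad = out < _MIN_SPEED
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < _MIN_SPEED
    return out


class _Walker:
    """Sequential 1-s stepping with chunked pre-drawn randomness."""

    def __init__(self, rng, x0, y0):
        self.rng = rng
        self.xs = [x0]
        self.ys = [y0]
        self.states = []
        self.trips = []
        self.patches = []

    @property
    def pos(self):
        return self.xs[-1], self.ys[-1]

    def emit(self, x, y, state, trip, patch):
        self.xs.append(x)
        self.ys.append(y)
        self.states.append(state)
        self.trips.append(trip)
        self.patches.append(patch)

    def commute(self, target, arrive_dist, speed_mean, speed_sd, heading_sd,
                trip, max_steps, label_patch=-1):
        """Target-directed walk: re-aim at the target each second with
        wrapped-normal heading noise. Returns steps taken."""
        tx, ty = target
        x, y = self.pos
        n = 0
        chunk = 2048
        while math.hypot(tx - x, ty - y) > arrive_dist:
            if n % chunk == 0:
                speeds = _draw_speeds(self.rng, speed_mean, speed_sd, chunk)
                noise = self.rng.normal(0.0, heading_sd, chunk)
            if n >= max_steps:
                raise UnreachablePatchError(
                    f"target {target} not reached within the allotted "
                    f"{max_steps} s of commuting")
            k = n % chunk
            hdg = math.atan2(ty - y, tx - x) + noise[k]
            v = speeds[k]
            step = min(v, math.hypot(tx - x, ty - y))  # do not overshoot the target
            x += step * math.cos(hdg)
            y += step * math.sin(hdg)
            self.emit(x, y, COMMUTE, trip, label_patch)
            n += 1
        return n

    def forage(self, patch: PatchSpec, patch_idx, duration_s, speed_mean,
               speed_sd, heading_sd, core_frac, trip):
        """Tortuous area-restricted search: a correlated random walk with
        a weak Ornstein-Uhlenbeck pull toward the patch core (nectar bats
        trapline around a flower cluster rather than diffusing freely),
        reflected at the patch boundary as a hard backstop. The pull rate
        is set so the stationary position sd is ``core_frac * radius``."""
        cx, cy = patch.center
        x, y = self.pos
        hdg = self.rng.uniform(-math.pi, math.pi)
        tau = 2.0 / heading_sd**2              # heading correlation time, s
        diffusion = speed_mean**2 * tau / 2.0  # m^2/s of the free walk
        pull = diffusion / (core_frac * patch.radius) ** 2
        nsec = int(round(duration_s))
        speeds = _draw_speeds(self.rng, speed_mean, speed_sd, nsec)
        turns = self.rng.normal(0.0, heading_sd, nsec)
        for k in range(nsec):
            hdg += turns[k]
            nx = x + speeds[k] * math.cos(hdg) - pull * (x - cx)
            ny = y + speeds[k] * math.sin(hdg) - pull * (y - cy)
            d = math.hypot(nx - cx, ny - cy)
            if d > patch.radius:       # reflect at the patch boundary
                f = (2.0 * patch.radius - d) / d
                nx = cx + f * (nx - cx)
                ny = cy + f * (ny - cy)
                hdg = math.atan2(ny - y, nx - x)
            x, y = nx, ny
            self.emit(x, y, FORAGE, trip, patch_idx)

    def dwell(self, x, y, duration_s, state, trip):
        for _ in range(int(round(duration_s))):
            self.emit(x, y, state, trip, -1)


def _plan_night(config: SimConfig, rng: np.random.Generator):
    """Allocate the night between commuting, foraging and roost dwells."""
    T = config.night_seconds
    dwells = rng.uniform(config.roost_dwell_range[0] * 60.0,
                         config.roost_dwell_range[1] * 60.0,
                         max(config.n_trips - 1, 0))
    commute_est = []
    for trip in config.trip_itineraries:
        pts = [(0.0, 0.0)] + [config.patches[i].center for i in trip] + [(0.0, 0.0)]
        dist = sum(math.hypot(b[0] - a[0], b[1] - a[1])
                   for a, b in zip(pts[:-1], pts[1:]))
        commute_est.append(dist / config.commute_speed_mean * _COMMUTE_SLACK)
    n_bouts = sum(len(t) for t in config.trip_itineraries)
    margin = 300.0
    budget = T - sum(commute_est) - float(dwells.sum()) - margin
    # patch residence bouts of 1-2.5 h; whatever night time is left over
    # becomes the final roost dwell (bats idle in the roost once fed)
    bout_s = rng.uniform(config.bout_range[0] * 60.0,
                         config.bout_range[1] * 60.0, n_bouts)
    if budget < _BOUT_FLOOR * n_bouts:
        worst = max(config.patches, key=lambda p: p.distance)
        raise UnreachablePatchError(
            f"itinerary does not fit the {T / 3600:.1f} h night: patch at "
            f"{worst.distance / 1000:.1f} km leaves {budget:.0f} s for "
            f"{n_bouts} foraging bout(s)")
    if bout_s.sum() > budget:
        bout_s *= budget / bout_s.sum()
    return dwells, bout_s


def simulate_night(config: SimConfig, seed: int | None = None) -> SimulatedNight:
    """Simulate one bat-night at 1-s resolution.

    The path starts and ends at the roost (origin). Behavioural truth is
    emitted per second; step ``i`` (from sample ``i`` to ``i+1``) carries
    the state of its destination sample.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    T = config.night_seconds
    dwells, bout_s = _plan_night(config, rng)
    walker = _Walker(rng, 0.0, 0.0)
    bout = 0
    for trip_no, itinerary in enumerate(config.trip_itineraries, start=1):
        for patch_idx in itinerary:
            patch = config.patches[patch_idx]
            dist = math.hypot(patch.center[0] - walker.pos[0],
                              patch.center[1] - walker.pos[1])
            max_steps = int(dist / config.commute_speed_mean * 3.0) + 600
            walker.commute(patch.center, 0.6 * patch.radius,
                           config.commute_speed_mean, config.commute_speed_sd,
                           config.commute_heading_sd, trip_no, max_steps)
            walker.forage(patch, patch_idx, bout_s[bout],
                          config.forage_speed_mean, config.forage_speed_sd,
                          config.forage_heading_sd, config.forage_core_frac,
                          trip_no)
            bout += 1
        dist_home = math.hypot(*walker.pos)
        max_steps = int(dist_home / config.commute_speed_mean * 3.0) + 600
        walker.commute((0.0, 0.0), config.commute_speed_mean,
                       config.commute_speed_mean, config.commute_speed_sd,
                       config.commute_heading_sd, trip_no, max_steps)
        # snap the final approach onto the roost itself
        walker.xs[-1], walker.ys[-1] = 0.0, 0.0
        if trip_no <= dwells.size:
            walker.dwell(0.0, 0.0, dwells[trip_no - 1], ROOST, 0)
    n_moving = len(walker.states)
    if n_moving > T:
        raise UnreachablePatchError(
            f"simulated activity ({n_moving} s) overran the {T} s night")
    walker.dwell(0.0, 0.0, T - n_moving, ROOST, 0)
    state = np.concatenate([[ROOST], np.asarray(walker.states, dtype=np.int8)])
    trip = np.concatenate([[0], np.asarray(walker.trips, dtype=np.int16)])
    patch = np.concatenate([[-1], np.asarray(walker.patches, dtype=np.int16)])
    truth = GroundTruth(state=state, trip=trip, patch=patch.astype(np.int16))
    return SimulatedNight(config=config,
                          t=np.arange(T + 1, dtype=float),
                          x=np.asarray(walker.xs), y=np.asarray(walker.ys),
                          truth=truth)


# ---------------------------------------------------------------------------
# GPS sampling

def schedule_seconds(config: SimConfig) -> np.ndarray:
    """Scheduled fix offsets (s) across the night, endpoints inclusive."""
    step = config.fix_interval * 60.0
    return np.arange(0.0, config.night_seconds + 0.5, step)


def sample_gps(night: SimulatedNight, config: SimConfig | None = None,
               seed: int | None = None) -> pd.DataFrame:
    """Sample the continuous path through the GPS duty-cycle model.

    Returns a Movebank-style table with one row per scheduled slot.
    Slots falling inside a roost dwell are emitted as invalid (the tag
    cannot see satellites inside the roost); every other slot fails
    independently with ``dropout_prob``. Valid fixes get isotropic
    Gaussian position error and are exported to WGS84 via the UTM zone
    of the roost.
    """
    config = config or night.config
    if seed is None:
        seed = (config.seed + 1_000_003) % 2**31
    rng = np.random.default_rng(seed)
    slots = schedule_seconds(config)
    if slots[-1] > night.t[-1] + 1e-9:
        raise ValueError("schedule extends past the simulated path")
    idx = np.clip(np.round(slots).astype(int), 0, night.t.size - 1)
    in_roost = night.truth.state[idx] == ROOST
    dropped = rng.random(slots.size) < config.dropout_prob
    valid = ~(in_roost | dropped)
    x = night.x[idx] + rng.normal(0.0, config.position_error_sd, slots.size)
    y = night.y[idx] + rng.normal(0.0, config.position_error_sd, slots.size)
    tm = TransverseMercator.for_point(*config.roost_lonlat)
    rx, ry = tm.forward(*config.roost_lonlat)
    lon, lat = tm.inverse(rx + x, ry + y)
    ts = config.night_start_utc() + pd.to_timedelta(slots, unit="s")
    out = pd.DataFrame({
        "timestamp": ts,
        "location-long": np.where(valid, lon, np.nan),
        "location-lat": np.where(valid, lat, np.nan),
        "individual-local-identifier": config.individual_id,
        "fix-status": np.where(valid, "valid", "invalid"),
    })
    return out


def truth_at_slots(night: SimulatedNight, config: SimConfig | None = None) -> pd.DataFrame:
    """Ground-truth state/trip/patch at each scheduled fix slot."""
    config = config or night.config
    slots = schedule_seconds(config)
    idx = np.clip(np.round(slots).astype(int), 0, night.t.size - 1)
    ts = config.night_start_utc() + pd.to_timedelta(slots, unit="s")
    return pd.DataFrame({
        "timestamp": ts,
        "state": np.vectorize(STATE_NAMES.get)(night.truth.state[idx]),
        "trip": night.truth.trip[idx],
        "patch": night.truth.patch[idx],
    })


# ---------------------------------------------------------------------------
# Rasters

def generate_landcover(extent, patches, background_class: str = "shrubland",
                       cell_size: float = 100.0, seed: int | None = None):
    """Categorical land-cover grid: patch circles carry their habitat class,
    the matrix carries ``background_class``. Classes are coded per
    ``LANDCOVER_CODES``; decode with ``CODE_TO_HABITAT``."""
    from .raster import Raster

    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    xmin, ymin, xmax, ymax = extent
    for p in patches:
        if not (xmin <= p.center[0] <= xmax and ymin <= p.center[1] <= ymax):
            raise ValueError(f"patch at {p.center} outside extent {extent}")
    ncols = int(math.ceil((xmax - xmin) / cell_size))
    nrows = int(math.ceil((ymax - ymin) / cell_size))
    grid = np.full((nrows, ncols), LANDCOVER_CODES[background_class], dtype=float)
    ras = Raster(values=grid, x0=xmin, y0=ymin, cell=cell_size)
    cx, cy = ras.cell_centers()
    for p in patches:
        inside = (cx - p.center[0]) ** 2 + (cy - p.center[1]) ** 2 <= p.radius**2
        ras.values[inside] = LANDCOVER_CODES[p.habitat]
    return ras


def generate_elevation(extent, cell_size: float = 100.0, base: float = 1950.0,
                       amplitude: float = 120.0, wavelength: float = 8000.0,
                       seed: int = 0):
    """Smooth seeded relief: a base level plus a few random cosine ridges."""
    from .raster import Raster

    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = extent
    ncols = int(math.ceil((xmax - xmin) / cell_size))
    nrows = int(math.ceil((ymax - ymin) / cell_size))
    ras = Raster(values=np.zeros((nrows, ncols)), x0=xmin, y0=ymin, cell=cell_size)
    cx, cy = ras.cell_centers()
    z = np.full_like(cx, base)
    n_waves = 6
    for _ in range(n_waves):
        theta = rng.uniform(0, 2 * math.pi)
        lam = wavelength * rng.uniform(0.5, 2.0)
        k = 2 * math.pi / lam
        phase = rng.uniform(0, 2 * math.pi)
        z += (amplitude / n_waves) * np.cos(
            k * (cx * math.cos(theta) + cy * math.sin(theta)) + phase)
    ras.values = z
    return ras


# ---------------------------------------------------------------------------
# Study-style cohorts

#: observed distribution of round trips per night (10/21, 8/21, 3/21 nights)
TRIP_COUNT_WEIGHTS = {1: 10 / 21, 2: 8 / 21, 3: 3 / 21}
#: observed habitat mix of foraging areas
HABITAT_WEIGHTS = {"shrubland": 0.46, "forest": 0.27, "farmland": 0.27}


def random_night_config(rng: np.random.Generator, individual_id: str = "2201",
                        fix_interval: float = 10.0,
                        dropout_prob: float = 0.47,
                        n_trips: int | None = None,
                        n_patches: int | None = None) -> SimConfig:
    """Draw one night's configuration under the emulated study conditions.

    Patches sit 13–40 km from the roost in a northward fan, with radii
    300–500 m and the observed habitat mix; itineraries are redrawn until
    the night can physically accommodate the commuting they imply.
    """
    if n_trips is None:
        counts = np.array(sorted(TRIP_COUNT_WEIGHTS))
        probs = np.array([TRIP_COUNT_WEIGHTS[c] for c in counts])
        n_trips = int(rng.choice(counts, p=probs / probs.sum()))
    if n_patches is None:
        n_patches = int(rng.integers(1, 4))
    habs = list(HABITAT_WEIGHTS)
    hab_p = np.array([HABITAT_WEIGHTS[h] for h in habs])
    for _ in range(200):
        patches = []
        for _ in range(n_patches):
            d = rng.uniform(13_000.0, 40_000.0)
            bearing = rng.uniform(math.radians(60), math.radians(120))  # northward fan
            patches.append(PatchSpec(
                center=(d * math.cos(bearing), d * math.sin(bearing)),
                radius=float(rng.uniform(300.0, 500.0)),
                habitat=str(rng.choice(habs, p=hab_p / hab_p.sum()))))
        itineraries = tuple((i % n_patches,) for i in range(n_trips))
        cfg = SimConfig(patches=tuple(patches), trip_itineraries=itineraries,
                        fix_interval=fix_interval, dropout_prob=dropout_prob,
                        individual_id=individual_id,
                        seed=int(rng.integers(0, 2**31 - 1)))
        try:
            _plan_night(cfg, np.random.default_rng(cfg.seed))
        except UnreachablePatchError:
            continue
        return cfg
    raise UnreachablePatchError("could not draw a feasible night in 200 tries")


def campaign_cohort_configs(seed: int, n_nights: int = 21) -> list[SimConfig]:
    """Configs emulating the deployed cohort: 21 one-night tracks, 10-min
    schedules for ~three quarters of tags and 15-min for the rest."""
    rng = np.random.default_rng(seed)
    n_coarse = round(n_nights * 5 / 21)    # the 15-min tags
    configs = []
    for i in range(n_nights):
        year = "21" if i < n_coarse else "22"
        interval = 15.0 if i < n_coarse else 10.0
        configs.append(random_night_config(
            rng, individual_id=f"{year}{i + 1:02d}", fix_interval=interval))
    return configs
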