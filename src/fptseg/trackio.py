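"""Reading, validating, filtering and projecting GPS fix tables.

Tracks arrive as Movebank-style CSV (``timestamp``, ``location-long``,
``location-lat``, ``individual-local-identifier``, ``fix-status``), one
row per scheduled fix with failed fixes flagged invalid. Analysis needs
planar metric coordinates, so tracks are projected into the UTM zone of
the roost; all timestamps are UTC internally and local clock windows
(GPS schedules, the early-evening exclusion) are converted through a
configured UTC offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .projection import TransverseMercator
from .raster import Raster

REQUIRED_COLUMNS = ("timestamp", "location-long", "location-lat",
                    "individual-local-identifier", "fix-status")

#: local clock window excluded near the tag-activation site
DEFAULT_EXCLUSION_WINDOW = ("20:00", "21:30")
DEFAULT_UTC_OFFSET = -6.0


@dataclass(frozen=True)
class Roost:
    """The central place. Planar coordinates are filled on projection."""

    lon: float
    lat: float
    x: float | None = None
    y: float | None = None

    def projected(self, tm: TransverseMercator) -> "Roost":
        x, y = tm.forward(self.lon, self.lat)
        return Roost(lon=self.lon, lat=self.lat, x=float(x), y=float(y))


@dataclass
class Track:
    """Ordered timestamped relocations for one individual-night(s).

    ``fixes`` columns: timestamp (tz-aware UTC), lon, lat, valid (bool),
    and after processing x, y (m) and elevation (m). Invalid fixes carry
    NaN coordinates and survive reading so filtering can count them.
    """

    individual_id: str
    fixes: pd.DataFrame
    fix_interval: float | None = None       # scheduled minutes, if inferable
    crs: TransverseMercator | None = None
    filter_counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.fixes) < 2:
            raise ValueError(f"track {self.individual_id}: needs >= 2 fixes")
        ts = self.fixes["timestamp"]
        if not ts.is_monotonic_increasing or ts.duplicated().any():
            raise ValueError(
                f"track {self.individual_id}: timestamps not strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def n_valid(self) -> int:
        return int(self.fixes["valid"].sum())

    def valid_only(self) -> pd.DataFrame:
        return self.fixes[self.fixes["valid"]].reset_index(drop=True)

    def seconds(self) -> np.ndarray:
        """Elapsed seconds of each fix since the first fix."""
        ts = self.fixes["timestamp"]
        return (ts - ts.iloc[0]).dt.total_seconds().to_numpy()

    def xy(self) -> tuple[np.ndarray, np.ndarray]:
        if "x" not in self.fixes:
            raise ValueError("track not projected; call project() first")
        return self.fixes["x"].to_numpy(), self.fixes["y"].to_numpy()

    def step_lengths(self) -> np.ndarray:
        """Euclidean distance (m) between consecutive fixes."""
        x, y = self.xy()
        return np.hypot(np.diff(x), np.diff(y))


def _infer_interval(ts: pd.Series) -> float | None:
    if len(ts) < 2:
        return None
    diffs = ts.diff().dt.total_seconds().dropna() / 60.0
    return float(round(diffs.min()))


def read_fixes(path: str | Path, episode_gap_hours: float = 12.0) -> list[Track]:
    """Read a Movebank-style CSV into raw (unfiltered) tracks.

    One Track per individual per contiguous tracking episode; episodes
    split at gaps longer than ``episode_gap_hours``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce")
        bad = int(parsed.isna().idxmax())
        raise ValueError(
            f"{path}: unparseable timestamp at row {bad + 2} "  # 1-based + header
            f"({df['timestamp'].iloc[bad]!r})") from None
    tracks = []
    for ind, sub in df.groupby("individual-local-identifier", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        gaps = sub["timestamp"].diff().dt.total_seconds() / 3600.0
        episode = (gaps > episode_gap_hours).cumsum().fillna(0)
        for _, ep in sub.groupby(episode):
            fixes = pd.DataFrame({
                "timestamp": ep["timestamp"].to_numpy(),
                "lon": ep["location-long"].to_numpy(dtype=float),
                "lat": ep["location-lat"].to_numpy(dtype=float),
                "valid": (ep["fix-status"].astype(str).str.lower() == "valid").to_numpy(),
            })
            fixes["timestamp"] = pd.to_datetime(fixes["timestamp"], utc=True)
            tracks.append(Track(individual_id=str(ind), fixes=fixes,
                                fix_interval=_infer_interval(fixes["timestamp"])))
    return tracks


def write_fixes(tracks: "list[Track] | Track", path: str | Path) -> None:
    """Write tracks back to the Movebank-style CSV dialect."""
    if isinstance(tracks, Track):
        tracks = [tracks]
    frames = []
    for tr in tracks:
        frames.append(pd.DataFrame({
            "timestamp": tr.fixes["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "location-long": tr.fixes["lon"],
            "location-lat": tr.fixes["lat"],
            "individual-local-identifier": tr.individual_id,
            "fix-status": np.where(tr.fixes["valid"], "valid", "invalid"),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")


def _approx_meters(lon, lat, lon0, lat0):
    """Local equirectangular distance in metres (adequate for km-scale
    proximity checks on unprojected fixes)."""
    kx = 111_320.0 * np.cos(np.radians(lat0))
    ky = 110_574.0
    return np.hypot((np.asarray(lon) - lon0) * kx, (np.asarray(lat) - lat0) * ky)


def filter_track(track: Track,
                 exclusion_window: tuple[str, str] = DEFAULT_EXCLUSION_WINDOW,
                 roost: Roost | None = None,
                 proximity: float = 1000.0,
                 utc_offset_hours: float = DEFAULT_UTC_OFFSET) -> Track:
    """Drop invalid fixes and early-evening fixes near the activation site.

    The activation-site anchor is the roost when given (tags are turned on
    at the roost), otherwise the night's first valid fix; fixes whose
    local clock time falls inside ``exclusion_window`` and that lie within
    ``proximity`` metres of the anchor are removed. Counts dropped by each
    rule are recorded on the returned track.
    """
    fixes = track.fixes
    n_invalid = int((~fixes["valid"]).sum())
    fixes = fixes[fixes["valid"]].reset_index(drop=True)
    if fixes.empty:
        raise ValueError(f"track {track.individual_id}: no valid fixes survive")
    if roost is not None:
        anchor = (roost.lon, roost.lat)
    else:
        anchor = (float(fixes["lon"].iloc[0]), float(fixes["lat"].iloc[0]))
    local = fixes["timestamp"] + pd.Timedelta(hours=utc_offset_hours)
    clock = local.dt.hour * 60 + local.dt.minute + local.dt.second / 60.0
    w0 = _clock_minutes(exclusion_window[0])
    w1 = _clock_minutes(exclusion_window[1])
    in_window = ((clock >= w0) & (clock <= w1) if w0 <= w1
                 else (clock >= w0) | (clock <= w1))
    near = _approx_meters(fixes["lon"], fixes["lat"], anchor[0], anchor[1]) <= proximity
    drop = (in_window & near).to_numpy()
    n_window = int(drop.sum())
    fixes = fixes[~drop].reset_index(drop=True)
    if len(fixes) < 2:
        raise ValueError(
            f"track {track.individual_id}: unusable after filtering "
            f"({n_invalid} invalid, {n_window} early-evening fixes dropped)")
    return Track(individual_id=track.individual_id, fixes=fixes,
                 fix_interval=track.fix_interval, crs=track.crs,
                 filter_counts={"invalid": n_invalid, "window": n_window})


def _clock_minutes(hhmm: str) -> float:
    h, m = hhmm.split(":")
    return int(h) * 60 + int(m)


def project(track: Track, projection: TransverseMercator | str | None = None) -> Track:
    """Fill planar x, y (m). Default frame: the UTM zone of the first fix."""
    fixes = track.fixes.copy()
    if projection is None:
        valid = fixes[fixes["valid"]]
        projection = TransverseMercator.for_point(
            float(valid["lon"].iloc[0]), float(valid["lat"].iloc[0]))
    elif isinstance(projection, str):
        projection = TransverseMercator.from_crs_id(projection)
    x = np.full(len(fixes), np.nan)
    y = np.full(len(fixes), np.nan)
    ok = fixes["valid"].to_numpy()
    if ok.any():
        x[ok], y[ok] = projection.forward(fixes.loc[ok, "lon"].to_numpy(),
                                          fixes.loc[ok, "lat"].to_numpy())
    fixes["x"] = x
    fixes["y"] = y
    return Track(individual_id=track.individual_id, fixes=fixes,
                 fix_interval=track.fix_interval, crs=projection,
                 filter_counts=dict(track.filter_counts))


@dataclass(frozen=True)
class GapStats:
    mean: float         # minutes
    sd: float
    max: float
    gaps: tuple         # (start timestamp, length minutes), sorted by start


def gap_stats(track: Track, threshold: float | None = None) -> GapStats:
    """Inter-fix interval statistics over valid fixes, in minutes.

    ``threshold`` (minutes) picks which intervals are reported as gaps;
    default 1.5x the scheduled interval when known, else 1.5x the median.
    """
    fixes = track.valid_only()
    if len(fixes) < 2:
        raise ValueError("gap_stats needs >= 2 valid fixes")
    ts = fixes["timestamp"]
    diffs = ts.diff().dt.total_seconds().dropna().to_numpy() / 60.0
    if threshold is None:
        base = track.fix_interval or float(np.median(diffs))
        threshold = 1.5 * base
    starts = ts.iloc[:-1].to_numpy()
    gaps = tuple((pd.Timestamp(s), float(d))
                 for s, d in zip(starts, diffs) if d > threshold)
    sd = float(np.std(diffs, ddof=1)) if diffs.size > 1 else 0.0
    return GapStats(mean=float(diffs.mean()), sd=sd, max=float(diffs.max()),
                    gaps=gaps)


def attach_elevation(track: Track, dem: Raster) -> Track:
    """Sample the DEM (nearest cell, half-open cells) at each projected fix."""
    x, y = track.xy()
    elev = dem.sample(x, y)
    outside = np.isnan(elev) & track.fixes["valid"].to_numpy()
    if outside.any():
        warnings.warn(f"track {track.individual_id}: {int(outside.sum())} "
                      f"fix(es) outside the DEM; elevation left missing",
                      stacklevel=2)
    fixes = track.fixes.copy()
    fixes["elevation"] = elev
    return Track(individual_id=track.individual_id, fixes=fixes,
                 fix_interval=track.fix_interval, crs=track.crs,
                 filter_counts=dict(track.filter_counts))
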