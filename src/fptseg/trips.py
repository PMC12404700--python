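"""Nightly trip decomposition and foraging-area characterisation.

A central-place forager's night decomposes into roost-to-roost round
trips separated by roost dwells, which the tag records as long gaps
(it cannot fix satellites inside the roost). A gap splits two trips
when it is long enough (>= 30 min) and the bat could plausibly have
reached the roost and returned within it at commuting speed.

Foraging areas are the qualifying foraging-flight segments: >= 30 min
span and >= 2 relocations. Each area is characterised by its centroid,
the track's own S(r)-peak radius r* (area = pi r*^2), distance from
the roost, cumulative search time, and the majority land-cover class
under its relocations; differences across habitat types are screened
with Kruskal-Wallis tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .raster import Raster
from .segmentation import FF, Segment, track_step_lengths
from .simulate import CODE_TO_HABITAT, HABITATS
from .trackio import Roost, Track

#: tie-break priority for habitat majority votes
HABITAT_PRIORITY = {"shrubland": 0, "forest": 1, "farmland": 2}

AREA_VARIABLES = ("roost_distance_km", "area_km2", "search_time_h")


@dataclass
class Trip:
    """One roost-to-roost excursion: a run of fixes between qualifying gaps."""

    track_id: str
    index: int                  # 1-based
    start: int                  # inclusive fix indices into the valid fixes
    end: int
    total_distance_km: float = np.nan
    mean_speed_ms: float = np.nan
    incomplete: bool = False    # single-fix trips carry no metrics
    area_ids: list = field(default_factory=list)

    @property
    def n_fixes(self) -> int:
        return self.end - self.start + 1


def split_trips(track: Track, roost: Roost, min_gap: float = 30.0,
                roost_buffer: float = 5000.0,
                commute_speed: float = 7.5) -> list[Trip]:
    """Split a night at gaps during which the bat was plausibly roosting.

    A gap separates two trips when the bat could have flown from the
    last fix to the roost, dwelt there at least ``min_gap`` minutes, and
    flown back out to the next fix: the gap minus the round-trip travel
    time (summed roost distances of the bracketing fixes over
    ``commute_speed``) must be >= ``min_gap``. Gaps >= ``min_gap`` whose
    bracketing fixes both already sit within ``roost_buffer`` of the
    roost split unconditionally. This rejects long fix-failure runs in
    mid-commute or mid-patch, which no roost visit could explain.
    """
    if roost.x is None or roost.y is None:
        raise ValueError("roost must be projected into the track frame")
    fixes = track.valid_only()
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    t = (fixes["timestamp"] - fixes["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    d_roost = np.hypot(x - roost.x, y - roost.y)
    gaps_s = np.diff(t)
    da, db = d_roost[:-1], d_roost[1:]
    residual_dwell = gaps_s - (da + db) / commute_speed
    at_roost = (da <= roost_buffer) & (db <= roost_buffer) & (gaps_s >= min_gap * 60.0)
    boundary = np.nonzero((residual_dwell >= min_gap * 60.0) | at_roost)[0]
    starts = np.concatenate([[0], boundary + 1])
    ends = np.concatenate([boundary, [len(fixes) - 1]])
    trips = [Trip(track_id=track.individual_id, index=k + 1,
                  start=int(a), end=int(b))
             for k, (a, b) in enumerate(zip(starts, ends))]
    return [trip_metrics(trip, track) for trip in trips]


def trip_metrics(trip: Trip, track: Track) -> Trip:
    """Total distance (km) and mean speed (m/s) over the trip's fixes."""
    fixes = track.valid_only()
    if trip.n_fixes < 2:
        trip.incomplete = True
        return trip
    steps = track_step_lengths(track)
    dist_m = float(steps[trip.start:trip.end].sum())
    t = (fixes["timestamp"] - fixes["timestamp"].iloc[0]).dt.total_seconds()
    elapsed = float(t.iloc[trip.end] - t.iloc[trip.start])
    trip.total_distance_km = dist_m / 1000.0
    trip.mean_speed_ms = dist_m / elapsed if elapsed > 0 else np.nan
    return trip


@dataclass
class ForagingArea:
    """A delineated patch of area-restricted search."""

    id: str
    track_id: str
    member_fixes: list              # indices into the valid fixes
    centroid: tuple[float, float]   # planar m
    r_star: float                   # the track's S(r)-peak radius, m
    area_km2: float
    search_time_h: float
    roost_distance_km: float = np.nan
    habitat: str | None = None
    n_segments: int = 1


def area_size(track_r_star: float) -> float:
    """Foraging-area size (km^2) from the track's S(r)-peak radius,
    reported to 2 decimals: area = pi r*^2."""
    return round(math.pi * (track_r_star / 1000.0) ** 2, 2)


def roost_distance(area: ForagingArea, roost: Roost) -> float:
    """Planar centroid-to-roost distance, km."""
    if roost.x is None or roost.y is None:
        raise ValueError("roost must be projected")
    return math.hypot(area.centroid[0] - roost.x,
                      area.centroid[1] - roost.y) / 1000.0


def search_time(area: ForagingArea) -> float:
    """Cumulative time (h) spent inside the area's member FF segment(s)."""
    return area.search_time_h


def find_foraging_areas(segments: list[Segment], track: Track, r_star: float,
                        min_duration: float = 30.0, min_fixes: int = 2,
                        merge: bool = True) -> list[ForagingArea]:
    """Qualify FF segments as foraging areas and optionally merge revisits.

    A segment qualifies when its member fixes span >= ``min_duration``
    minutes and number >= ``min_fixes``. With ``merge``, areas of the same
    track whose centroids lie within r* of each other are folded into one
    (a patch revisited across the night is one area, not several).
    """
    fixes = track.valid_only()
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    ts = (fixes["timestamp"] - fixes["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    areas = []
    for seg in segments:
        if seg.mode != FF:
            continue
        span_min = (ts[seg.end] - ts[seg.start]) / 60.0
        n = seg.end - seg.start + 1
        if span_min < min_duration or n < min_fixes:
            continue
        members = list(range(seg.start, seg.end + 1))
        areas.append(ForagingArea(
            id=f"{track.individual_id}-a{len(areas) + 1}",
            track_id=track.individual_id, member_fixes=members,
            centroid=(float(x[members].mean()), float(y[members].mean())),
            r_star=float(r_star), area_km2=area_size(r_star),
            search_time_h=float(seg.duration_h)))
    if merge:
        areas = _merge_revisits(areas, x, y)
    return areas


def _merge_revisits(areas: list[ForagingArea], x, y) -> list[ForagingArea]:
    """Union-merge areas whose centroids fall within r* of each other,
    iterated to a fixed point."""
    changed = True
    while changed:
        changed = False
        out: list[ForagingArea] = []
        for area in areas:
            target = None
            for prev in out:
                dx = area.centroid[0] - prev.centroid[0]
                dy = area.centroid[1] - prev.centroid[1]
                if math.hypot(dx, dy) <= max(area.r_star, prev.r_star):
                    target = prev
                    break
            if target is None:
                out.append(area)
            else:
                members = sorted(set(target.member_fixes) | set(area.member_fixes))
                target.member_fixes = members
                target.centroid = (float(x[members].mean()), float(y[members].mean()))
                target.search_time_h += area.search_time_h
                target.n_segments += area.n_segments
                changed = True
        areas = out
    for k, area in enumerate(areas, start=1):
        area.id = f"{area.track_id}-a{k}"
    return areas


def assign_habitat(area: ForagingArea, landcover: Raster, track: Track) -> str | None:
    """Majority land-cover class under the area's member relocations.

    Fixes outside the raster (or over unclassified background) are
    excluded from the vote; ties break by the fixed priority
    shrubland > forest > farmland. Returns None when no fix can vote.
    """
    fixes = track.valid_only()
    idx = np.asarray(area.member_fixes)
    codes = landcover.sample(fixes["x"].to_numpy()[idx], fixes["y"].to_numpy()[idx])
    votes: dict[str, int] = {}
    for code in codes[np.isfinite(codes)]:
        name = CODE_TO_HABITAT.get(int(code))
        if name in HABITATS:
            votes[name] = votes.get(name, 0) + 1
    if not votes:
        area.habitat = None
        return None
    best = max(votes, key=lambda h: (votes[h], -HABITAT_PRIORITY[h]))
    area.habitat = best
    return best


@dataclass
class HabitatSummary:
    counts: dict
    fractions: dict
    group_stats: pd.DataFrame           # habitat x variable mean/sd
    tests: pd.DataFrame | None          # Kruskal-Wallis H, df, p per variable


def habitat_tests(areas: list[ForagingArea]) -> HabitatSummary:
    """Counts/fractions per habitat and Kruskal-Wallis screens of
    roost distance, area size and search time across habitat types.
    With fewer than two nonempty habitat groups the tests are omitted
    but the summary is still produced."""
    classified = [a for a in areas if a.habitat in HABITATS]
    counts = {h: sum(1 for a in classified if a.habitat == h) for h in HABITATS}
    total = max(sum(counts.values()), 1)
    fractions = {h: c / total for h, c in counts.items()}
    rows = []
    for h in HABITATS:
        sub = [a for a in classified if a.habitat == h]
        for var in AREA_VARIABLES:
            vals = np.array([getattr(a, var) for a in sub], dtype=float)
            vals = vals[np.isfinite(vals)]
            rows.append({"habitat": h, "variable": var, "n": vals.size,
                         "mean": float(vals.mean()) if vals.size else np.nan,
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0})
    group_stats = pd.DataFrame(rows)
    groups_present = [h for h in HABITATS if counts[h] > 0]
    tests = None
    if len(groups_present) >= 2:
        test_rows = []
        for var in AREA_VARIABLES:
            samples = [[getattr(a, var) for a in classified if a.habitat == h]
                       for h in groups_present]
            try:
                with np.errstate(invalid="ignore"):
                    h_stat, p = stats.kruskal(*samples)
            except ValueError:
                h_stat, p = np.nan, np.nan
            if not np.isfinite(h_stat):     # all values tied: no separation
                h_stat, p = 0.0, 1.0
            test_rows.append({"variable": var, "H": float(h_stat),
                              "df": len(groups_present) - 1, "p": float(p)})
        tests = pd.DataFrame(test_rows)
    return HabitatSummary(counts=counts, fractions=fractions,
                          group_stats=group_stats, tests=tests)


@dataclass
class NightSummary:
    track_id: str
    total_distance_km: float
    moving_time_h: float            # in-trip elapsed time (dwells excluded)
    night_time_h: float             # first-to-last fix, dwells included
    mean_speed_ms: float
    n_trips: int
    n_areas: int
    cf_time_h: float
    ff_time_h: float
    cf_fraction_moving: float
    ff_fraction_moving: float
    ff_fraction_night: float
    main_area_time_h: float         # search time in the busiest area
    main_area_fraction_ff: float


def night_summary(track: Track, labels: np.ndarray, trips: list[Trip],
                  areas: list[ForagingArea]) -> NightSummary:
    """Per-night report: totals, mode time budget, and the main area.

    CF/FF time is accumulated over steps inside trips only (each step
    carries its left fix's label), so CF + FF time equals moving time
    exactly; fractions over the dwell-inclusive night span are reported
    alongside since field summaries differ on the denominator.
    """
    fixes = track.valid_only()
    t = (fixes["timestamp"] - fixes["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    steps = track_step_lengths(track)
    labels = np.asarray(labels)
    in_trip = np.zeros(steps.size, dtype=bool)
    for trip in trips:
        in_trip[trip.start:trip.end] = True
    dt = np.diff(t)
    cf_s = float(dt[in_trip & (labels[:-1] == "CF")].sum())
    ff_s = float(dt[in_trip & (labels[:-1] == "FF")].sum())
    moving_s = float(dt[in_trip].sum())
    night_s = float(t[-1] - t[0])
    total_km = float(steps.sum()) / 1000.0
    main_h = max((a.search_time_h for a in areas), default=0.0)
    return NightSummary(
        track_id=track.individual_id,
        total_distance_km=total_km,
        moving_time_h=moving_s / 3600.0,
        night_time_h=night_s / 3600.0,
        mean_speed_ms=total_km * 1000.0 / moving_s if moving_s > 0 else np.nan,
        n_trips=len(trips),
        n_areas=len(areas),
        cf_time_h=cf_s / 3600.0,
        ff_time_h=ff_s / 3600.0,
        cf_fraction_moving=cf_s / moving_s if moving_s > 0 else np.nan,
        ff_fraction_moving=ff_s / moving_s if moving_s > 0 else np.nan,
        ff_fraction_night=ff_s / night_s if night_s > 0 else np.nan,
        main_area_time_h=main_h,
        main_area_fraction_ff=main_h * 3600.0 / ff_s if ff_s > 0 else np.nan)
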