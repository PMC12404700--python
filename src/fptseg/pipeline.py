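"""End-to-end orchestration: simulate -> read -> filter -> project ->
FPT -> segment -> trips/areas -> cohort summaries.

The pipeline mirrors how a tracking campaign is analysed: every track
contributes a per-night S(r) profile and optimal radius; the cohort
mean radius then drives a final FPT pass and the 2.7141 log-FPT
threshold splits commuting from foraging; trips, foraging areas,
habitat assignment and the cohort statistics follow. A run is fully
determined by its config and seed.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fpt import RadiusGrid, optimal_radius, passage_times, population_radius, var_log_fpt
from .geo import areas_geojson, segments_geojson
from .projection import TransverseMercator
from .raster import Raster
from .segmentation import (DEFAULT_THRESHOLD, build_segments, classify_modes,
                           compare_modes, segments_frame)
from .simulate import (PatchSpec, SimConfig, generate_elevation, generate_landcover,
                       campaign_cohort_configs, sample_gps, simulate_night, truth_at_slots)
from .trackio import (Roost, Track, attach_elevation, filter_track, gap_stats,
                      project, read_fixes, write_fixes)
from .trips import (ForagingArea, assign_habitat, find_foraging_areas, habitat_tests,
                    night_summary, roost_distance, split_trips)

log = logging.getLogger("fptseg")


@dataclass
class PipelineConfig:
    """Everything a run needs; serialisable to/from YAML."""

    seed: int = 0
    output_dir: str = "out"
    tracks_csv: str | None = None           # analyze an existing fix table ...
    n_nights: int = 21                      # ... or simulate a cohort
    dropout_prob: float = 0.47
    roost_lon: float = -98.60
    roost_lat: float = 20.45
    projection: str | None = None           # CRS id; default roost UTM zone
    radius_min: float = 300.0
    radius_max: float = 500.0
    radius_step: float = 10.0
    threshold: float = DEFAULT_THRESHOLD
    exclusion_window: tuple[str, str] = ("20:00", "21:30")
    exclusion_proximity: float = 1000.0
    utc_offset_hours: float = -6.0
    min_gap: float = 30.0                   # minutes
    roost_buffer: float = 5000.0            # m
    trip_commute_speed: float = 7.5         # m/s, roost-reachability speed
    min_area_duration: float = 30.0         # minutes
    min_area_fixes: int = 2
    merge_areas: bool = True
    landcover: str | None = None            # ASCII grid paths
    dem: str | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "exclusion_window" in raw:
            raw["exclusion_window"] = tuple(raw["exclusion_window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusion_window"] = list(d["exclusion_window"])
        return d

    def grid(self) -> RadiusGrid:
        return RadiusGrid.from_range(self.radius_min, self.radius_max, self.radius_step)


@dataclass
class RunReport:
    """Per-track and cohort tables plus per-stage counters."""

    version: str
    config: dict
    per_track: pd.DataFrame
    cohort: dict
    mode_tests: pd.DataFrame | None
    habitat_summary: object | None
    counts: dict
    errors: list = field(default_factory=list)

    def to_text(self) -> str:
        lines = [f"fptseg {self.version} run report",
                 f"seed: {self.config.get('seed')}", ""]
        lines.append("-- per-stage counts --")
        for k, v in self.counts.items():
            lines.append(f"{k}: {v}")
        lines.append("")
        lines.append("-- cohort statistics (mean +- sd unless noted) --")
        for k, v in self.cohort.items():
            if isinstance(v, tuple):
                lines.append(f"{k}: {v[0]:.2f} +- {v[1]:.2f}")
            elif isinstance(v, float):
                lines.append(f"{k}: {v:.2f}")
            else:
                lines.append(f"{k}: {v}")
        if self.mode_tests is not None:
            lines += ["", "-- commuting vs foraging (Mann-Whitney on per-track means) --",
                      self.mode_tests.to_string(index=False)]
        if self.habitat_summary is not None:
            hs = self.habitat_summary
            lines += ["", "-- foraging areas by habitat --",
                      f"counts: {hs.counts}",
                      "fractions: " + str({k: round(v, 2) for k, v in hs.fractions.items()}),
                      hs.group_stats.to_string(index=False)]
            if hs.tests is not None:
                lines += ["", "-- Kruskal-Wallis across habitats --",
                          hs.tests.to_string(index=False)]
        if self.errors:
            lines += ["", "-- per-track errors --"] + [str(e) for e in self.errors]
        return "\n".join(lines) + "\n"


def simulate_cohort(config: PipelineConfig, out_dir: Path):
    """Write a synthetic cohort (tracks, truth, rasters) under out_dir."""
    out_dir.mkdir(parents=True, exist_ok=True)
    sim_configs = campaign_cohort_configs(config.seed, config.n_nights)
    sim_configs = [dataclasses.replace(c, dropout_prob=config.dropout_prob,
                                       roost_lonlat=(config.roost_lon, config.roost_lat))
                   for c in sim_configs]
    nights = [simulate_night(c) for c in sim_configs]
    tracks = []
    truths = []
    for cfg, night in zip(sim_configs, nights):
        gps = sample_gps(night)
        gps = gps.assign(timestamp=gps["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"))
        tracks.append(gps)
        tru = truth_at_slots(night)
        tru = tru.assign(timestamp=tru["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
                         individual=cfg.individual_id)
        truths.append(tru)
    pd.concat(tracks, ignore_index=True).to_csv(out_dir / "tracks.csv", index=False,
                                                float_format="%.12g")
    pd.concat(truths, ignore_index=True).to_csv(out_dir / "truth.csv", index=False)
    # shared rasters over the union of patches, in the roost UTM frame
    tm = TransverseMercator.for_point(config.roost_lon, config.roost_lat)
    rx, ry = tm.forward(config.roost_lon, config.roost_lat)
    all_patches = [PatchSpec(center=(p.center[0] + rx, p.center[1] + ry),
                             radius=p.radius, habitat=p.habitat)
                   for c in sim_configs for p in c.patches]
    xs = [p.center[0] for p in all_patches] + [rx]
    ys = [p.center[1] for p in all_patches] + [ry]
    pad = 2000.0
    extent = (min(xs) - pad, min(ys) - pad, max(xs) + pad, max(ys) + pad)
    lc = generate_landcover(extent, all_patches, cell_size=100.0)
    dem = generate_elevation(extent, cell_size=200.0, seed=config.seed)
    lc.write(out_dir / "landcover.asc")
    dem.write(out_dir / "dem.asc")
    with open(out_dir / "sim_config.yaml", "w") as fh:
        yaml.safe_dump({"n_nights": config.n_nights, "seed": config.seed,
                        "dropout_prob": config.dropout_prob,
                        "individuals": [c.individual_id for c in sim_configs]}, fh)
    return out_dir / "tracks.csv", nights, sim_configs


@dataclass
class TrackResult:
    track: Track
    profile: object
    r_star: float
    labels: np.ndarray = None
    segments: list = None
    trips: list = None
    areas: list = None
    summary: object = None


def run(config: PipelineConfig) -> RunReport:
    """Execute the full chain and write all stage outputs.

    Per-track failures are recorded and the cohort continues; conservation
    identities (segment lengths vs track length, CF+FF vs moving time) are
    asserted at run time for every track.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts = {}
    errors = []

    if config.tracks_csv is None:
        tracks_path, _, _ = simulate_cohort(config, out_dir / "sim")
        landcover_path = out_dir / "sim" / "landcover.asc"
        dem_path = out_dir / "sim" / "dem.asc"
    else:
        tracks_path = Path(config.tracks_csv)
        landcover_path = Path(config.landcover) if config.landcover else None
        dem_path = Path(config.dem) if config.dem else None

    raw_tracks = read_fixes(tracks_path)
    counts["tracks_read"] = len(raw_tracks)
    counts["fixes_read"] = sum(len(t) for t in raw_tracks)
    counts["fixes_valid"] = sum(t.n_valid for t in raw_tracks)

    tm = (TransverseMercator.from_crs_id(config.projection) if config.projection
          else TransverseMercator.for_point(config.roost_lon, config.roost_lat))
    roost = Roost(lon=config.roost_lon, lat=config.roost_lat).projected(tm)
    landcover = Raster.read(landcover_path) if landcover_path else None
    dem = Raster.read(dem_path) if dem_path else None

    results: list[TrackResult] = []
    for raw in raw_tracks:
        try:
            tr = filter_track(raw, config.exclusion_window, roost,
                              config.exclusion_proximity, config.utc_offset_hours)
            tr = project(tr, tm)
            if dem is not None:
                tr = attach_elevation(tr, dem)
            profile = var_log_fpt(tr, config.grid())
            results.append(TrackResult(track=tr, profile=profile,
                                       r_star=optimal_radius(profile)))
        except (ValueError, RuntimeError) as exc:
            errors.append(f"{raw.individual_id} [scale selection]: {exc}")
            log.warning("track %s dropped: %s", raw.individual_id, exc)
    counts["tracks_analysed"] = len(results)
    if not results:
        raise RuntimeError("no track survived filtering and scale selection")

    mean_r, sd_r = population_radius([r.r_star for r in results])

    all_areas: list[ForagingArea] = []
    summaries = []
    for res in results:
        tr = res.track
        try:
            fpt = passage_times(tr, mean_r)
            res.labels = classify_modes(fpt, config.threshold)
            res.segments = build_segments(res.labels, tr)
            res.trips = split_trips(tr, roost, config.min_gap,
                                    config.roost_buffer, config.trip_commute_speed)
            res.areas = find_foraging_areas(res.segments, tr, res.r_star,
                                            config.min_area_duration,
                                            config.min_area_fixes,
                                            config.merge_areas)
            for area in res.areas:
                area.roost_distance_km = roost_distance(area, roost)
                if landcover is not None:
                    assign_habitat(area, landcover, tr)
            res.summary = night_summary(tr, res.labels, res.trips, res.areas)
            _assert_conserved(res)
            all_areas.extend(res.areas)
            summaries.append(res.summary)
        except (ValueError, RuntimeError) as exc:
            errors.append(f"{tr.individual_id} [segmentation]: {exc}")
            log.warning("track %s failed segmentation: %s", tr.individual_id, exc)

    counts["segments"] = sum(len(r.segments or []) for r in results)
    counts["trips"] = sum(len(r.trips or []) for r in results)
    counts["foraging_areas"] = len(all_areas)

    per_track = pd.DataFrame([{
        "track": s.track_id,
        "r_star_m": next(r.r_star for r in results if r.track.individual_id == s.track_id),
        "total_distance_km": s.total_distance_km,
        "moving_time_h": s.moving_time_h,
        "mean_speed_ms": s.mean_speed_ms,
        "n_trips": s.n_trips,
        "n_areas": s.n_areas,
        "cf_time_h": s.cf_time_h,
        "ff_time_h": s.ff_time_h,
        "cf_fraction_moving": s.cf_fraction_moving,
    } for s in summaries])

    cohort = _cohort_stats(per_track, [r.r_star for r in results], all_areas)
    mode_tests = None
    seg_by_track = {r.track.individual_id: r.segments for r in results if r.segments}
    n_both = sum(1 for segs in seg_by_track.values()
                 if {s.mode for s in segs} == {"CF", "FF"})
    if n_both >= 2:
        try:
            mode_tests = compare_modes(seg_by_track)
        except ValueError as exc:
            errors.append(f"[mode comparison]: {exc}")
    habitat = habitat_tests(all_areas) if all_areas else None

    _write_outputs(out_dir, results, all_areas, per_track, tm)
    report = RunReport(version=__version__, config=config.to_dict(),
                       per_track=per_track, cohort=cohort, mode_tests=mode_tests,
                       habitat_summary=habitat, counts=counts, errors=errors)
    (out_dir / "report.txt").write_text(report.to_text())
    return report


def _assert_conserved(res: TrackResult) -> None:
    """Run-time conservation checks; a violation is a pipeline bug."""
    from .segmentation import track_step_lengths
    total_km = float(track_step_lengths(res.track).sum()) / 1000.0
    seg_km = sum(s.total_length_km for s in res.segments)
    if not math.isclose(seg_km, total_km, rel_tol=1e-9, abs_tol=1e-12):
        raise RuntimeError(f"segment lengths {seg_km} != track length {total_km}")
    s = res.summary
    if not math.isclose(s.cf_time_h + s.ff_time_h, s.moving_time_h,
                        rel_tol=1e-9, abs_tol=1e-12):
        raise RuntimeError("CF + FF time != moving time")


def _cohort_stats(per_track: pd.DataFrame, r_stars, areas) -> dict:
    def ms(col):
        v = per_track[col].to_numpy(dtype=float)
        v = v[np.isfinite(v)]
        return (float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0)

    mean_r, sd_r = population_radius(r_stars)
    out = {
        "n_tracks": int(len(per_track)),
        "optimal_radius_m": (mean_r, sd_r),
        "total_distance_km": ms("total_distance_km"),
        "mean_speed_ms": ms("mean_speed_ms"),
        "trips_per_night": ms("n_trips"),
        "areas_per_night": ms("n_areas"),
        "cf_fraction_moving": ms("cf_fraction_moving"),
        "n_foraging_areas": int(len(areas)),
    }
    if areas:
        sizes = np.array([a.area_km2 for a in areas])
        dists = np.array([a.roost_distance_km for a in areas])
        times = np.array([a.search_time_h for a in areas])
        out["area_km2"] = (float(sizes.mean()), float(sizes.std(ddof=1)) if sizes.size > 1 else 0.0)
        out["area_km2_min"] = float(sizes.min())
        out["area_km2_max"] = float(sizes.max())
        out["roost_distance_km"] = (float(dists.mean()), float(dists.std(ddof=1)) if dists.size > 1 else 0.0)
        out["search_time_h"] = (float(times.mean()), float(times.std(ddof=1)) if times.size > 1 else 0.0)
    return out


def _write_outputs(out_dir: Path, results, all_areas, per_track, tm) -> None:
    segs = [s for r in results if r.segments for s in r.segments]
    if segs:
        segments_frame(segs).to_csv(out_dir / "segments.csv", index=False)
    trips_rows = [{
        "track": t.track_id, "trip": t.index, "start": t.start, "end": t.end,
        "distance_km": t.total_distance_km, "mean_speed_ms": t.mean_speed_ms,
        "incomplete": t.incomplete,
    } for r in results if r.trips for t in r.trips]
    if trips_rows:
        pd.DataFrame(trips_rows).to_csv(out_dir / "trips.csv", index=False)
    area_rows = [{
        "id": a.id, "track": a.track_id, "habitat": a.habitat,
        "centroid_x": a.centroid[0], "centroid_y": a.centroid[1],
        "r_star_m": a.r_star, "area_km2": a.area_km2,
        "roost_distance_km": a.roost_distance_km, "search_time_h": a.search_time_h,
        "n_segments": a.n_segments,
    } for a in all_areas]
    if area_rows:
        pd.DataFrame(area_rows).to_csv(out_dir / "areas.csv", index=False)
        areas_geojson(all_areas, tm, out_dir / "areas.geojson")
    profiles = pd.concat([r.profile.to_frame().assign(track=r.track.individual_id)
                          for r in results], ignore_index=True)
    profiles.to_csv(out_dir / "fpt_profiles.csv", index=False)
    per_track.to_csv(out_dir / "per_track.csv", index=False)
    for r in results:
        if r.segments:
            segments_geojson(r.segments, r.track,
                             out_dir / f"segments_{r.track.individual_id}.geojson")
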