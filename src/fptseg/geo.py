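"""GeoJSON export of segments, trips and foraging areas (WGS84)."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from shapely.geometry import Point, mapping

from .projection import TransverseMercator
from .segmentation import Segment
from .trackio import Track
from .trips import ForagingArea


def _feature(geometry, properties):
    return {"type": "Feature", "geometry": geometry, "properties": properties}


def _dump(features, path):
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=1)


def segments_geojson(segments: list[Segment], track: Track, path: str | Path) -> None:
    """One LineString per segment, in geographic coordinates."""
    fixes = track.valid_only()
    lon = fixes["lon"].to_numpy()
    lat = fixes["lat"].to_numpy()
    feats = []
    for seg in segments:
        idx = np.arange(seg.start, min(seg.end + 2, len(fixes)))  # include boundary step
        coords = [[round(float(lon[i]), 8), round(float(lat[i]), 8)] for i in idx]
        if len(coords) < 2:
            coords = coords * 2
        feats.append(_feature(
            {"type": "LineString", "coordinates": coords},
            {"track": seg.track_id, "mode": seg.mode,
             "length_km": seg.total_length_km, "duration_h": seg.duration_h,
             "speed_ms": seg.speed_ms}))
    _dump(feats, path)


def areas_geojson(areas: list[ForagingArea], tm: TransverseMercator,
                  path: str | Path) -> None:
    """One polygon per area: the circle of radius r* about the centroid."""
    feats = []
    for area in areas:
        circle = Point(area.centroid).buffer(area.r_star, quad_segs=24)
        xs, ys = np.asarray(circle.exterior.coords).T
        lon, lat = tm.inverse(xs, ys)
        ring = [[round(float(a), 8), round(float(b), 8)] for a, b in zip(lon, lat)]
        feats.append(_feature(
            {"type": "Polygon", "coordinates": [ring]},
            {"id": area.id, "track": area.track_id, "habitat": area.habitat,
             "r_star_m": area.r_star, "area_km2": area.area_km2,
             "roost_distance_km": area.roost_distance_km,
             "search_time_h": area.search_time_h}))
    _dump(feats, path)
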