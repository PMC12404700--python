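"""Planar projection of geographic coordinates.

First-passage-time radii, step lengths and roost distances are metric
quantities, so tracks are analysed in a single projected frame per study
region: the UTM zone containing the roost (WGS84 ellipsoid, transverse
Mercator with the standard 0.9996 scale factor and 500 km false easting).

The forward/inverse transverse Mercator uses the classical series
expansions (Snyder, *Map Projections — A Working Manual*, USGS PP 1395),
accurate to well under a millimetre within a zone; the round trip
lon/lat -> x,y -> lon/lat closes to < 1e-6 m in practice.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

# WGS84 ellipsoid
_A = 6378137.0
_F = 1.0 / 298.257223563
_E2 = _F * (2.0 - _F)
_EP2 = _E2 / (1.0 - _E2)
_K0 = 0.9996
_FALSE_E = 500_000.0
_FALSE_N_SOUTH = 10_000_000.0

# meridian-arc series coefficients
_M0 = 1.0 - _E2 / 4.0 - 3.0 * _E2**2 / 64.0 - 5.0 * _E2**3 / 256.0
_M2 = 3.0 * _E2 / 8.0 + 3.0 * _E2**2 / 32.0 + 45.0 * _E2**3 / 1024.0
_M4 = 15.0 * _E2**2 / 256.0 + 45.0 * _E2**3 / 1024.0
_M6 = 35.0 * _E2**3 / 3072.0
_E1 = (1.0 - math.sqrt(1.0 - _E2)) / (1.0 + math.sqrt(1.0 - _E2))


def _meridian_arc(phi):
    return _A * (_M0 * phi - _M2 * np.sin(2 * phi) + _M4 * np.sin(4 * phi)
                 - _M6 * np.sin(6 * phi))


def utm_zone(lon: float, lat: float) -> tuple[int, bool]:
    """UTM zone number and hemisphere (north=True) containing a point."""
    zone = int(math.floor((lon + 180.0) / 6.0)) % 60 + 1
    return zone, lat >= 0.0


@dataclass(frozen=True)
class TransverseMercator:
    """A UTM-style transverse Mercator frame, identified by an EPSG string.

    ``crs_id`` follows the usual "EPSG:326xx" (north) / "EPSG:327xx"
    (south) convention so configs can declare the frame portably.
    """

    zone: int
    north: bool = True

    @property
    def lon0(self) -> float:
        return -183.0 + 6.0 * self.zone

    @property
    def crs_id(self) -> str:
        return f"EPSG:{32600 + self.zone if self.north else 32700 + self.zone}"

    @classmethod
    def for_point(cls, lon: float, lat: float) -> "TransverseMercator":
        zone, north = utm_zone(lon, lat)
        return cls(zone=zone, north=north)

    @classmethod
    def from_crs_id(cls, crs_id: str) -> "TransverseMercator":
        code = int(str(crs_id).upper().replace("EPSG:", ""))
        if 32601 <= code <= 32660:
            return cls(zone=code - 32600, north=True)
        if 32701 <= code <= 32760:
            return cls(zone=code - 32700, north=False)
        raise ValueError(f"unsupported CRS {crs_id!r}: expected a UTM/WGS84 "
                         f"code EPSG:326xx or EPSG:327xx")

    def forward(self, lon, lat):
        """Geographic degrees -> easting/northing metres (vectorised)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 180.0):
            raise ValueError("lon/lat out of range")
        dlon = np.abs(((lon - self.lon0) + 180.0) % 360.0 - 180.0)
        if np.any(dlon > 6.0):
            warnings.warn(
                "coordinates fall outside the declared UTM zone's validity "
                "band; distances may be distorted", stacklevel=2)
        phi = np.radians(lat)
        lam = np.radians(lon)
        lam0 = math.radians(self.lon0)
        sin_phi, cos_phi, tan_phi = np.sin(phi), np.cos(phi), np.tan(phi)
        nu = _A / np.sqrt(1.0 - _E2 * sin_phi**2)
        T = tan_phi**2
        C = _EP2 * cos_phi**2
        Aa = (lam - lam0) * cos_phi
        M = _meridian_arc(phi)
        x = _K0 * nu * (Aa + (1 - T + C) * Aa**3 / 6.0
                        + (5 - 18 * T + T**2 + 72 * C - 58 * _EP2) * Aa**5 / 120.0)
        y = _K0 * (M + nu * tan_phi * (Aa**2 / 2.0
                   + (5 - T + 9 * C + 4 * C**2) * Aa**4 / 24.0
                   + (61 - 58 * T + T**2 + 600 * C - 330 * _EP2) * Aa**6 / 720.0))
        x = x + _FALSE_E
        if not self.north:
            y = y + _FALSE_N_SOUTH
        return x, y

    def inverse(self, x, y):
        """Easting/northing metres -> geographic degrees (vectorised)."""
        x = np.asarray(x, dtype=float) - _FALSE_E
        y = np.asarray(y, dtype=float)
        if not self.north:
            y = y - _FALSE_N_SOUTH
        M = y / _K0
        mu = M / (_A * _M0)
        phi1 = (mu + (3 * _E1 / 2 - 27 * _E1**3 / 32) * np.sin(2 * mu)
                + (21 * _E1**2 / 16 - 55 * _E1**4 / 32) * np.sin(4 * mu)
                + (151 * _E1**3 / 96) * np.sin(6 * mu)
                + (1097 * _E1**4 / 512) * np.sin(8 * mu))
        sin1, cos1, tan1 = np.sin(phi1), np.cos(phi1), np.tan(phi1)
        C1 = _EP2 * cos1**2
        T1 = tan1**2
        N1 = _A / np.sqrt(1.0 - _E2 * sin1**2)
        R1 = _A * (1.0 - _E2) / (1.0 - _E2 * sin1**2) ** 1.5
        D = x / (N1 * _K0)
        phi = phi1 - (N1 * tan1 / R1) * (
            D**2 / 2.0
            - (5 + 3 * T1 + 10 * C1 - 4 * C1**2 - 9 * _EP2) * D**4 / 24.0
            + (61 + 90 * T1 + 298 * C1 + 45 * T1**2 - 252 * _EP2
               - 3 * C1**2) * D**6 / 720.0)
        lam = (D - (1 + 2 * T1 + C1) * D**3 / 6.0
               + (5 - 2 * C1 + 28 * T1 - 3 * C1**2 + 8 * _EP2
                  + 24 * T1**2) * D**5 / 120.0) / cos1
        lon = self.lon0 + np.degrees(lam)
        lat = np.degrees(phi)
        return lon, lat
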