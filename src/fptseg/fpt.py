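"""First Passage Time and the variance-of-log-FPT scale selection curve.

For each relocation, the first passage time t(r) is the time the path
takes to traverse a circle of radius r centred on that relocation: the
forward component runs from the fix until the path first crosses the
circle ahead, the backward component symmetrically toward the start,
and t(r) is their sum. Large t(r) marks area-restricted search.

The path between fixes is modelled as piecewise linear at constant
speed per step, so crossings are exact segment-circle intersections
with linear time interpolation. A track-level profile
S(r) = Var[log t(r)] (natural log, minutes, n-1 denominator) is scanned
over a radius grid; its peak r* is the characteristic scale of
area-restricted search, and the mean r* across individuals is the
single radius used for behavioural classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trackio import Track


@dataclass(frozen=True)
class RadiusGrid:
    """Strictly increasing candidate radii (m)."""

    radii: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.radii, dtype=float)
        if r.ndim != 1 or r.size == 0 or r[0] <= 0 or np.any(np.diff(r) <= 0):
            raise ValueError("radii must be strictly increasing and positive")
        object.__setattr__(self, "radii", r)

    @classmethod
    def from_range(cls, r_min: float = 300.0, r_max: float = 500.0,
                   step: float = 10.0) -> "RadiusGrid":
        return cls(np.arange(r_min, r_max + step / 2, step))


@dataclass
class FptSeries:
    """Per-fix passage times (minutes) at one radius; NaN where the path
    ends or starts before crossing the circle."""

    radius: float
    t: np.ndarray
    forward: np.ndarray
    backward: np.ndarray

    def log_t(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.log(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius": self.radius, "fix": np.arange(self.t.size),
                             "forward_min": self.forward,
                             "backward_min": self.backward, "t_min": self.t})


@dataclass
class VarLogProfile:
    """S(r) = Var[log t(r)] per radius, with the count of defined fixes."""

    radii: np.ndarray
    s: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"radius": self.radii, "s": self.s,
                             "n_defined": self.counts})


def _track_arrays(track: Track):
    fixes = track.valid_only()
    if len(fixes) < 2:
        raise ValueError("passage times need >= 2 valid fixes")
    if "x" not in fixes:
        raise ValueError("track must be planar-projected before FPT")
    x = fixes["x"].to_numpy()
    y = fixes["y"].to_numpy()
    t = (fixes["timestamp"] - fixes["timestamp"].iloc[0]).dt.total_seconds().to_numpy()
    return x, y, t


def _crossing_fraction(ax, ay, bx, by, cx, cy, r):
    """Fraction s in (0, 1] where segment A->B crosses the circle (C, r),
    A inside, B outside. Single outward root of the quadratic."""
    dx, dy = bx - ax, by - ay
    fx, fy = ax - cx, ay - cy
    a = dx * dx + dy * dy
    b = 2.0 * (fx * dx + fy * dy)
    c = fx * fx + fy * fy - r * r
    disc = b * b - 4.0 * a * c
    return (-b + np.sqrt(max(disc, 0.0))) / (2.0 * a)


def _passage_from_arrays(x, y, t, dist, r):
    """Forward/backward components (minutes) at every fix for one radius.

    ``dist`` is the precomputed pairwise fix-distance matrix, reused
    across radii; the first fix outside the circle locates the crossing
    segment exactly (a chord with both endpoints inside a circle cannot
    leave it).
    """
    n = x.size
    fwd = np.full(n, np.nan)
    bwd = np.full(n, np.nan)
    for i in range(n):
        outside = dist[i] > r
        ahead = np.nonzero(outside[i + 1:])[0]
        if ahead.size:
            j = i + 1 + int(ahead[0])          # first fix beyond r, forward
            s = _crossing_fraction(x[j - 1], y[j - 1], x[j], y[j],
                                   x[i], y[i], r)
            fwd[i] = (t[j - 1] + s * (t[j] - t[j - 1]) - t[i]) / 60.0
        behind = np.nonzero(outside[:i])[0]
        if behind.size:
            j = int(behind[-1])                # last fix beyond r, backward
            s = _crossing_fraction(x[j + 1], y[j + 1], x[j], y[j],
                                   x[i], y[i], r)
            bwd[i] = (t[i] - t[j + 1] + s * (t[j + 1] - t[j])) / 60.0
    return fwd, bwd


def passage_times(track: Track, r: float) -> FptSeries:
    """First passage times at radius ``r`` for every valid fix.

    t(r) = forward + backward; undefined (NaN) wherever the path ends or
    starts before crossing — in particular backward at the first fix and
    forward at the last.
    """
    if r <= 0:
        raise ValueError("radius must be positive")
    x, y, t = _track_arrays(track)
    dist = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    fwd, bwd = _passage_from_arrays(x, y, t, dist, r)
    return FptSeries(radius=float(r), t=fwd + bwd, forward=fwd, backward=bwd)


def var_log_fpt(track: Track, grid: RadiusGrid | None = None) -> VarLogProfile:
    """S(r) over the radius grid; NaN where < 2 fixes have defined t(r)."""
    grid = grid or RadiusGrid.from_range()
    x, y, t = _track_arrays(track)
    dist = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :])
    s = np.full(grid.radii.size, np.nan)
    counts = np.zeros(grid.radii.size, dtype=int)
    for k, r in enumerate(grid.radii):
        fwd, bwd = _passage_from_arrays(x, y, t, dist, r)
        tr = fwd + bwd
        defined = tr[np.isfinite(tr)]
        counts[k] = defined.size
        if defined.size >= 2:
            s[k] = float(np.var(np.log(defined), ddof=1))
    return VarLogProfile(radii=grid.radii.copy(), s=s, counts=counts)


def optimal_radius(profile: VarLogProfile) -> float:
    """argmax of S(r); ties and the argmax itself resolve toward the
    smallest radius; radii with undefined S are skipped."""
    if not np.isfinite(profile.s).any():
        raise ValueError("S(r) undefined at every radius")
    return float(profile.radii[np.nanargmax(profile.s)])


def population_radius(r_stars) -> tuple[float, float]:
    """Mean and sample SD of per-track optimal radii; the mean is the
    single radius used for the final FPT pass before thresholding."""
    r = np.asarray(list(r_stars), dtype=float)
    if r.size == 0:
        raise ValueError("need at least one optimal radius")
    sd = float(np.std(r, ddof=1)) if r.size > 1 else 0.0
    return float(r.mean()), sd
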