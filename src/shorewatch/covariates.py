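"""Topographic, tidal and temporal covariates.

Derives the habitat-model covariates from three inputs: a 50 m depth
raster, half-hourly surface-current snapshots per tidal state (u/v
components on a 300 m grid), and a tide table of high-water events.

Key quantities
--------------
* Slope/aspect by Horn's 3x3 method; aspect is the downslope azimuth in
  degrees clockwise from north.
* Neighbourhood SD over a cell and its ``k`` nearest neighbours (default
  k=5, rook neighbours before diagonals) for slope and current roughness.
* The tidal stratification parameter ``log10(h / U^3)`` (depth over cubed
  current amplitude): low values are tidally mixed, ~2.75 marks frontal
  boundaries, high values remain stratified in summer.
* Temporal covariates: tidal state (signed hours to nearest high water,
  period 12.42 h) and lunar cycle (signed days to nearest neap tide,
  period 14.77 d), both circular downstream.

Current direction follows the oceanographic *toward* convention
(degrees clockwise from true north, the direction the water flows to).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "TideTable",
    "CurrentSnapshot",
    "CovariateVector",
    "EnvironmentBundle",
    "terrain_slope",
    "terrain_aspect",
    "neighborhood_sd",
    "decompose_current",
    "spatial_sd_speed",
    "tidal_stratification",
    "mean_stratification",
    "stratification_regime",
    "temporal_covariates",
    "interpolate_current",
    "sample_covariates",
    "temporal_covariates_frame",
    "sample_covariates_frame",
]

TIDAL_PERIOD_H = 12.42       #: semidiurnal (M2) period, hours
LUNAR_PERIOD_D = 14.77       #: spring-neap cycle, days
TIDAL_STATE_RANGE = TIDAL_PERIOD_H / 2.0    # +- 6.21 h
LUNAR_CYCLE_RANGE = LUNAR_PERIOD_D / 2.0    # +- 7.385 d
DEFAULT_FLOOR_U = 0.01       #: m/s floor guarding h/U^3 against zero currents

#: Neighbour offsets (row towards north = -1) in the deterministic order
#: rook (N, E, S, W) then diagonals (NE, SE, SW, NW).
_NEIGHBOR_ORDER = [(-1, 0), (0, 1), (1, 0), (0, -1),
                   (-1, 1), (1, 1), (1, -1), (-1, -1)]


class EmptyDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# tide table

@dataclass
class TideTable:
    """High-water events and the derived neap calendar.

    ``hw_times`` must be strictly increasing with ~12.42 h spacing;
    ``hw_heights`` are metres above extreme low tide. ``neap_dates`` (one
    per spring-neap cycle, the day of minimum tidal range) may be supplied
    or derived from the height envelope.
    """

    hw_times: pd.DatetimeIndex
    hw_heights: np.ndarray
    neap_dates: list[pd.Timestamp] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hw_times = pd.DatetimeIndex(self.hw_times)
        self.hw_heights = np.asarray(self.hw_heights, dtype=float)
        if len(self.hw_times) != len(self.hw_heights):
            raise ValueError("hw_times and hw_heights length mismatch")
        dt_h = np.diff(self.hw_times.view("int64")) / 3.6e12
        if len(dt_h) and (np.any(dt_h <= 0) or np.any(np.abs(dt_h - TIDAL_PERIOD_H) > 1.5)):
            raise ValueError("HW times must increase with ~12.42 h spacing")
        if np.any(self.hw_heights <= 0):
            raise ValueError("HW heights must be positive")
        if not self.neap_dates:
            self.neap_dates = self._derive_neap_dates()
        self.neap_dates = [pd.Timestamp(d) for d in self.neap_dates]

    def _derive_neap_dates(self) -> list[pd.Timestamp]:
        """Time of minimum HW height per spring-neap cycle (range proxy).

        Local minima of the HW-height envelope, refined to sub-tide
        precision by a parabola through the minimum and its neighbours.
        """
        if len(self.hw_times) < int(LUNAR_PERIOD_D):
            return []
        h = self.hw_heights
        t_ns = self.hw_times.view("int64").astype(float)
        neaps: list[pd.Timestamp] = []
        for i in range(1, len(h) - 1):
            if h[i] <= h[i - 1] and h[i] < h[i + 1]:
                # parabolic vertex through the three points (uniform spacing)
                denom = h[i - 1] - 2 * h[i] + h[i + 1]
                shift = 0.0 if denom == 0 else 0.5 * (h[i - 1] - h[i + 1]) / denom
                t_min = t_ns[i] + shift * (t_ns[i + 1] - t_ns[i])
                cand = pd.Timestamp(int(t_min))
                if not neaps or (cand - neaps[-1]).total_seconds() >= 10 * 86400:
                    neaps.append(cand)
        return neaps

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        return self.hw_times[0], self.hw_times[-1]

    def height_above_LW(self, t: datetime) -> float:
        """Tidal height (m above extreme low tide) at time ``t``.

        Cosine profile between high waters: the nearest HW's height at the
        event, falling to 0 at the intervening low water.
        """
        t = pd.Timestamp(t)
        i = int(np.argmin(np.abs((self.hw_times - t).view("int64"))))
        dt_h = (t - self.hw_times[i]).total_seconds() / 3600.0
        return float(self.hw_heights[i] * 0.5 * (1 + np.cos(2 * np.pi * dt_h / TIDAL_PERIOD_H)))

    def to_csv(self, path) -> None:
        pd.DataFrame({"time": self.hw_times, "height": self.hw_heights}).to_csv(
            path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TideTable":
        df = pd.read_csv(path, parse_dates=["time"])
        return cls(pd.DatetimeIndex(df["time"]), df["height"].to_numpy())


# ---------------------------------------------------------------------------
# current snapshots

@dataclass
class CurrentSnapshot:
    """Surface current field (u east, v north, m/s) at one tidal state."""

    tidal_state: float          # hours relative to HW
    u: RasterGrid
    v: RasterGrid

    def __post_init__(self) -> None:
        if abs(self.tidal_state) > 6.5:
            raise ValueError("tidal_state must lie within +-6.5 h of HW")
        if not self.u.congruent(self.v):
            raise ValueError("u and v grids must be congruent")
        speed = np.hypot(self.u.values, self.v.values)
        if np.nanmax(speed) >= 5.0:
            raise ValueError("current speeds must stay below 5 m/s")

    def speed(self) -> RasterGrid:
        return self.u.copy_with(np.hypot(self.u.values, self.v.values))


# ---------------------------------------------------------------------------
# terrain derivatives (Horn 3x3)

def _horn_gradients(grid: RasterGrid) -> tuple[np.ndarray, np.ndarray]:
    z = grid.values
    if np.all(np.isnan(z)):
        raise EmptyDataError("all-nodata raster")
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise EmptyDataError("need at least a 3x3 raster")
    p = np.pad(z, 1, constant_values=np.nan)
    # window letters: a b c / d e f / g h i, row 0 = north
    a = p[:-2, :-2]; b = p[:-2, 1:-1]; c = p[:-2, 2:]
    d = p[1:-1, :-2];                  f = p[1:-1, 2:]
    g = p[2:, :-2];  h = p[2:, 1:-1];  i = p[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * grid.cell_size)
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * grid.cell_size)
    return gx, gy


def terrain_slope(depth: RasterGrid) -> RasterGrid:
    """Seabed slope in degrees (0-90), Horn's method; borders -> nodata."""
    gx, gy = _horn_gradients(depth)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    return depth.copy_with(slope)


def terrain_aspect(depth: RasterGrid, flat_tol: float = 1e-12) -> RasterGrid:
    """Downslope azimuth in degrees clockwise from north; flat cells -> NaN.

    Depth is positive down, so the downslope direction (steepest descent of
    the seabed surface) is the direction of *increasing* depth.
    """
    gx, gy = _horn_gradients(depth)
    aspect = np.degrees(np.arctan2(gx, gy)) % 360.0
    aspect[np.hypot(gx, gy) <= flat_tol] = np.nan
    return depth.copy_with(aspect)


def neighborhood_sd(grid: RasterGrid, k_neighbors: int = 5,
                    ddof: int = 1) -> RasterGrid:
    """Per-cell SD over the cell and its ``k`` nearest neighbours.

    Neighbours are taken in the deterministic order N, E, S, W, NE, SE,
    SW, NW (rook before diagonal); cells whose stencil reaches outside the
    grid or touches nodata become nodata.
    """
    if not 1 <= k_neighbors <= 8:
        raise ValueError("k_neighbors must be in 1..8")
    z = grid.values
    p = np.pad(z, 1, constant_values=np.nan)
    stack = [z]
    for dr, dc in _NEIGHBOR_ORDER[:k_neighbors]:
        stack.append(p[1 + dr:1 + dr + z.shape[0], 1 + dc:1 + dc + z.shape[1]])
    arr = np.stack(stack)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sd = np.std(arr, axis=0, ddof=ddof)
    sd[np.any(np.isnan(arr), axis=0)] = np.nan
    return grid.copy_with(sd)


# ---------------------------------------------------------------------------
# currents

def decompose_current(speed, direction_toward):
    """Split speed/direction into (u east, v north); toward convention."""
    speed = np.asarray(speed, dtype=float)
    if np.any(speed < 0):
        raise ValueError("speed must be non-negative")
    rad = np.radians(np.asarray(direction_toward, dtype=float))
    u = speed * np.sin(rad)
    v = speed * np.cos(rad)
    if u.ndim == 0:
        return float(u), float(v)
    return u, v


def spatial_sd_speed(u: RasterGrid, v: RasterGrid,
                     k_neighbors: int = 5) -> RasterGrid:
    """Spatial variation in current speed: sqrt(SD_x^2 + SD_y^2)."""
    if not u.congruent(v):
        raise ValueError("u and v grids must be congruent")
    sd_x = neighborhood_sd(u, k_neighbors).values
    sd_y = neighborhood_sd(v, k_neighbors).values
    return u.copy_with(np.hypot(sd_x, sd_y))


# ---------------------------------------------------------------------------
# stratification

def tidal_stratification(h, U, floor_U: float = DEFAULT_FLOOR_U):
    """Simpson-Hunter stratification parameter log10(h / U^3).

    ``U`` is floored at ``floor_U`` m/s so that slack-water snapshots do
    not produce infinities.
    """
    h = np.asarray(h, dtype=float)
    U = np.asarray(U, dtype=float)
    if np.any(h[np.isfinite(h)] <= 0):
        raise ValueError("depth must be positive")
    out = np.log10(h / np.maximum(U, floor_U) ** 3)
    return float(out) if out.ndim == 0 else out


def _resample_to(grid_300: RasterGrid, target: RasterGrid) -> np.ndarray:
    gx, gy = target.center_mesh()
    return np.asarray(grid_300.sample_bilinear(gx.ravel(), gy.ravel())).reshape(gx.shape)


def mean_stratification(h: RasterGrid, snapshots: list[CurrentSnapshot],
                        floor_U: float = DEFAULT_FLOOR_U) -> RasterGrid:
    """log10(h / Ubar^3) with Ubar the tidal-cycle mean speed per cell.

    Current components are resampled bilinearly from the 300 m snapshot
    grid to the depth grid before the speed is formed, then averaged over
    the supplied snapshots (which should span one full tidal cycle).
    """
    if len(snapshots) < 2:
        raise ValueError("need at least two snapshots spanning the cycle")
    speeds = []
    for snap in snapshots:
        uu = _resample_to(snap.u, h)
        vv = _resample_to(snap.v, h)
        speeds.append(np.hypot(uu, vv))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ubar = np.nanmean(np.stack(speeds), axis=0)
    return h.copy_with(tidal_stratification(h.values, ubar, floor_U))


_REGIME_LABELS = ("mixed", "switching", "frontal_boundary",
                  "stratified", "strongly_stratified")


def stratification_regime(value: float) -> str:
    """Classify a log10(h/U^3) value into a mixing regime.

    Below 2.3 the column stays tidally mixed; 2.3-2.75 can switch between
    mixed and stratified over the spring-neap cycle; 2.75 marks the
    frontal boundary; 2.75-3.5 remains stratified in summer; above 3.5 is
    strongly stratified.
    """
    if not np.isfinite(value):
        raise ValueError("regime requires a finite value")
    if value < 2.3:
        return "mixed"
    if value < 2.75:
        return "switching"
    if value == 2.75:
        return "frontal_boundary"
    if value <= 3.5:
        return "stratified"
    return "strongly_stratified"


# ---------------------------------------------------------------------------
# temporal covariates

@dataclass(frozen=True)
class TemporalCovariates:
    tidal_state: float      # hours, signed, in [-6.21, 6.21]
    lunar_cycle: float      # days, signed, in [-7.385, 7.385]
    day_of_year: int
    hour_of_day: float
    year: int


def temporal_covariates(t: datetime, tide: TideTable) -> TemporalCovariates:
    """Tidal state, lunar cycle and calendar covariates at time ``t``."""
    t = pd.Timestamp(t)
    lo, hi = tide.span
    if not (lo - pd.Timedelta(hours=TIDAL_STATE_RANGE)
            <= t <= hi + pd.Timedelta(hours=TIDAL_STATE_RANGE)):
        raise ValueError(f"time {t} outside tide table span {lo}..{hi}")
    dt_h = (t - tide.hw_times).view("int64") / 3.6e12
    tidal_state = float(dt_h[np.argmin(np.abs(dt_h))])
    tidal_state = float(np.clip(tidal_state, -TIDAL_STATE_RANGE, TIDAL_STATE_RANGE))
    if tide.neap_dates:
        dt_d = np.array([(t - d).total_seconds() / 86400.0 for d in tide.neap_dates])
        lunar = float(dt_d[np.argmin(np.abs(dt_d))])
        lunar = float(np.clip(lunar, -LUNAR_CYCLE_RANGE, LUNAR_CYCLE_RANGE))
    else:
        lunar = np.nan
    return TemporalCovariates(
        tidal_state=tidal_state,
        lunar_cycle=lunar,
        day_of_year=int(t.dayofyear),
        hour_of_day=float(t.hour + t.minute / 60.0 + t.second / 3600.0),
        year=int(t.year),
    )


def interpolate_current(snapshots: list[CurrentSnapshot],
                        tidal_state: float) -> tuple[RasterGrid, RasterGrid]:
    """Linear interpolation of u and v between bracketing tidal states."""
    snaps = sorted(snapshots, key=lambda s: s.tidal_state)
    states = np.array([s.tidal_state for s in snaps])
    if tidal_state < states[0] or tidal_state > states[-1]:
        warnings.warn(f"tidal state {tidal_state:+.2f} h outside snapshot "
                      "range; clamping", stacklevel=2)
        tidal_state = float(np.clip(tidal_state, states[0], states[-1]))
    j = int(np.searchsorted(states, tidal_state, side="right"))
    j = min(max(j, 1), len(snaps) - 1)
    t0, t1 = states[j - 1], states[j]
    w = 0.0 if t1 == t0 else (tidal_state - t0) / (t1 - t0)
    u = snaps[0].u.copy_with((1 - w) * snaps[j - 1].u.values + w * snaps[j].u.values)
    v = snaps[0].v.copy_with((1 - w) * snaps[j - 1].v.values + w * snaps[j].v.values)
    return u, v


# ---------------------------------------------------------------------------
# covariate sampling

@dataclass
class CovariateVector:
    """All covariates of one space-time record."""

    depth: float
    slope: float
    sd_slope: float
    aspect: float
    sd_current_speed: float
    tidal_stratification: float
    mean_stratification: float
    tidal_state: float
    lunar_cycle: float
    day_of_year: int
    hour_of_day: float
    year: int
    x: float
    y: float
    current_direction: float
    current_speed: float = np.nan
    sea_state: int | None = None
    site: str | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)

    @property
    def valid(self) -> bool:
        core = (self.depth, self.slope, self.sd_slope, self.sd_current_speed,
                self.tidal_stratification, self.mean_stratification)
        return all(np.isfinite(v) for v in core)


@dataclass
class EnvironmentBundle:
    """Precomputed covariate surfaces plus the dynamic inputs."""

    depth: RasterGrid
    slope: RasterGrid
    sd_slope: RasterGrid
    aspect: RasterGrid
    sd_current_speed: RasterGrid
    mean_strat: RasterGrid
    snapshots: list[CurrentSnapshot]
    tide: TideTable
    floor_U: float = DEFAULT_FLOOR_U

    @classmethod
    def build(cls, depth: RasterGrid, snapshots: list[CurrentSnapshot],
              tide: TideTable, k_neighbors: int = 5,
              floor_U: float = DEFAULT_FLOOR_U) -> "EnvironmentBundle":
        slope = terrain_slope(depth)
        sd_slope = neighborhood_sd(slope, k_neighbors)
        aspect = terrain_aspect(depth)
        # cycle-average spatial roughness of the current field, on 50 m
        sd_stack = [
            _resample_to(spatial_sd_speed(s.u, s.v, k_neighbors), depth)
            for s in snapshots
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sd_current = depth.copy_with(np.nanmean(np.stack(sd_stack), axis=0))
        mstrat = mean_stratification(depth, snapshots, floor_U)
        return cls(depth, slope, sd_slope, aspect, sd_current, mstrat,
                   snapshots, tide, floor_U)


def temporal_covariates_frame(times, tide: TideTable) -> pd.DataFrame:
    """Vectorised :func:`temporal_covariates` over an array of times."""
    times = pd.DatetimeIndex(times)
    lo, hi = tide.span
    pad = pd.Timedelta(hours=TIDAL_STATE_RANGE)
    if times.min() < lo - pad or times.max() > hi + pad:
        raise ValueError("times outside tide table span")
    t_ns = times.view("int64")
    hw_ns = tide.hw_times.view("int64")
    j = np.clip(np.searchsorted(hw_ns, t_ns), 1, len(hw_ns) - 1)
    before = t_ns - hw_ns[j - 1]
    after = t_ns - hw_ns[j]
    dt_ns = np.where(np.abs(before) <= np.abs(after), before, after)
    tidal_state = np.clip(dt_ns / 3.6e12, -TIDAL_STATE_RANGE, TIDAL_STATE_RANGE)
    if tide.neap_dates:
        neap_ns = np.sort(np.array([pd.Timestamp(d).value for d in tide.neap_dates]))
        k = np.clip(np.searchsorted(neap_ns, t_ns), 1, len(neap_ns) - 1)
        nb = t_ns - neap_ns[k - 1]
        na = t_ns - neap_ns[k]
        dn = np.where(np.abs(nb) <= np.abs(na), nb, na)
        lunar = np.clip(dn / 8.64e13, -LUNAR_CYCLE_RANGE, LUNAR_CYCLE_RANGE)
    else:
        lunar = np.full(len(times), np.nan)
    return pd.DataFrame({
        "tidal_state": tidal_state,
        "lunar_cycle": lunar,
        "day_of_year": times.dayofyear,
        "hour_of_day": times.hour + times.minute / 60.0 + times.second / 3600.0,
        "year": times.year,
    })


def sample_covariates_frame(x, y, times, env: EnvironmentBundle,
                            sea_state=None, site=None) -> pd.DataFrame:
    """Vectorised :func:`sample_covariates` for arrays of points/times.

    Points are grouped by their bracketing snapshot pair so current
    interpolation is done per group rather than per record.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out = temporal_covariates_frame(times, env.tide)
    snaps = sorted(env.snapshots, key=lambda s: s.tidal_state)
    states = np.array([s.tidal_state for s in snaps])
    ts = np.clip(out["tidal_state"].to_numpy(), states[0], states[-1])
    j = np.clip(np.searchsorted(states, ts, side="right"), 1, len(snaps) - 1)
    w = (ts - states[j - 1]) / (states[j] - states[j - 1])
    u = np.empty(len(x))
    v = np.empty(len(x))
    for jj in np.unique(j):
        m = j == jj
        u0 = np.atleast_1d(snaps[jj - 1].u.sample_bilinear(x[m], y[m]))
        u1 = np.atleast_1d(snaps[jj].u.sample_bilinear(x[m], y[m]))
        v0 = np.atleast_1d(snaps[jj - 1].v.sample_bilinear(x[m], y[m]))
        v1 = np.atleast_1d(snaps[jj].v.sample_bilinear(x[m], y[m]))
        u[m] = (1 - w[m]) * u0 + w[m] * u1
        v[m] = (1 - w[m]) * v0 + w[m] * v1
    speed = np.hypot(u, v)
    depth = np.atleast_1d(env.depth.sample_bilinear(x, y))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tstrat = np.where(
            np.isfinite(depth) & (depth > 0),
            np.log10(np.maximum(depth, 1e-12)
                     / np.maximum(speed, env.floor_U) ** 3), np.nan)
        direction = np.where(speed > 0,
                             np.degrees(np.arctan2(u, v)) % 360.0, np.nan)
    out.insert(0, "depth", depth)
    out["slope"] = np.atleast_1d(env.slope.sample_bilinear(x, y))
    out["sd_slope"] = np.atleast_1d(env.sd_slope.sample_bilinear(x, y))
    out["aspect"] = np.atleast_1d(env.aspect.sample_nearest(x, y))
    out["sd_current_speed"] = np.atleast_1d(env.sd_current_speed.sample_bilinear(x, y))
    out["tidal_stratification"] = tstrat
    out["mean_stratification"] = np.atleast_1d(env.mean_strat.sample_bilinear(x, y))
    out["x"] = x
    out["y"] = y
    out["current_direction"] = direction
    out["current_speed"] = speed
    if sea_state is not None:
        out["sea_state"] = sea_state
    if site is not None:
        out["site"] = site
    core = ["depth", "slope", "sd_slope", "sd_current_speed",
            "tidal_stratification", "mean_stratification"]
    out["valid"] = np.isfinite(out[core].to_numpy()).all(axis=1)
    return out


def sample_covariates(p, t: datetime, env: EnvironmentBundle,
                      sea_state: int | None = None,
                      site: str | None = None) -> CovariateVector:
    """Sample the full covariate vector at a local point and time.

    Raster surfaces are sampled bilinearly; currents are interpolated to
    the tidal state of ``t`` and sampled at ``p``. Records hitting nodata
    are flagged via :attr:`CovariateVector.valid` and should be excluded
    downstream (with the count logged by the caller).
    """
    x, y = (p.x, p.y) if hasattr(p, "x") else (float(p[0]), float(p[1]))
    temp = temporal_covariates(t, env.tide)
    u_g, v_g = interpolate_current(env.snapshots, temp.tidal_state)
    u = u_g.sample_bilinear(x, y)
    v = v_g.sample_bilinear(x, y)
    speed = float(np.hypot(u, v))
    direction = float(np.degrees(np.arctan2(u, v)) % 360.0) if speed > 0 else np.nan
    depth = env.depth.sample_bilinear(x, y)
    tstrat = (tidal_stratification(depth, speed, env.floor_U)
              if np.isfinite(depth) and depth > 0 else np.nan)
    return CovariateVector(
        depth=depth,
        slope=env.slope.sample_bilinear(x, y),
        sd_slope=env.sd_slope.sample_bilinear(x, y),
        aspect=env.aspect.sample_nearest(x, y),
        sd_current_speed=env.sd_current_speed.sample_bilinear(x, y),
        tidal_stratification=tstrat,
        mean_stratification=env.mean_strat.sample_bilinear(x, y),
        tidal_state=temp.tidal_state,
        lunar_cycle=temp.lunar_cycle,
        day_of_year=temp.day_of_year,
        hour_of_day=temp.hour_of_day,
        year=temp.year,
        x=x, y=y,
        current_direction=direction,
        current_speed=speed,
        sea_state=sea_state,
        site=site,
    )
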