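"""Synthetic shore-based survey studies with known truth.

Generates a complete study around an island in a rectilinear semidiurnal
tidal regime: bathymetry with a shallow gully east of the island, a tide
table with spring-neap modulation, half-hourly current snapshots with a
flood-phase wake eddy, a four-platform scan schedule with a Markov
sea-state process, and sightings drawn from an inhomogeneous Poisson
point process whose log-intensity is a stated function of the covariates,
thinned by a sea-state-dependent detection function (certain detection up
to the inflection radius, linear decline to zero at twice that radius).

The generator's defaults are the study conditions every downstream test
and recovery experiment runs under; the truth record carries the exact
coefficients used so model recovery can be checked.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .covariates import (CurrentSnapshot, EnvironmentBundle, TideTable,
                         LUNAR_PERIOD_D, TIDAL_PERIOD_H,
                         temporal_covariates_frame)
from .geolocation import (GeodeticConfig, Platform, TransverseMercator,
                          corrected_platform_height, distance_to_reticles)
from .raster import RasterGrid

__all__ = [
    "SyntheticScenario",
    "make_tide_table",
    "make_bathymetry",
    "make_current_cycle",
    "make_effort_schedule",
    "simulate_dataset",
    "default_platforms",
]


@dataclass
class SyntheticScenario:
    """All knobs of one synthetic study; the defaults ARE the conditions."""

    seed: int = 0
    # domain (local metres) and grids
    extent: tuple[float, float, float, float] = (-5000.0, 5000.0, -4000.0, 4000.0)
    cell_size: float = 50.0
    current_cell_size: float = 300.0
    # island and bathymetry
    island_semi_axes: tuple[float, float] = (1300.0, 500.0)
    west_depth: float = 45.0
    east_depth: float = 14.0
    gully_center: tuple[float, float] = (2600.0, 200.0)
    gully_extra_depth: float = 6.0
    gully_sigma: tuple[float, float] = (900.0, 350.0)
    # tide
    days: int = 30
    start: datetime = field(default_factory=lambda: datetime(2004, 8, 1, 0, 0))
    hw_height_mean: float = 3.0
    spring_neap_amplitude: float = 1.0
    # currents
    current_axis_deg: float = 315.0     # flood flows toward NW
    slack_offset_h: float = -4.0        # LWS at HW-4
    peak_speed: float = 2.6             # m/s, capped below the 3 m/s maximum
    eddy_strength: float = 0.8
    eddy_center: tuple[float, float] = (-2400.0, 400.0)
    eddy_sigma: float = 900.0
    # effort
    scans_per_day: int = 50             # per platform, 10-min slots from 08:00
    sea_state_persistence: float = 0.9
    # truth: per-species log-intensity (per m^2 per scan)
    intercepts: dict = field(default_factory=lambda: {
        "porpoise": -15.2, "rissos": -19.0})
    effects: dict = field(default_factory=lambda: {
        "porpoise": {"depth": ("linear_std", 0.5),
                     "tidal_state": ("cosine", 0.6)},
        "rissos": {"depth": ("linear_std", -0.4),
                   "tidal_state": ("cosine", 0.3)},
    })
    depth_std_center: float = 25.0      # standardisation constants for the
    depth_std_scale: float = 10.0       # 'linear_std' depth effect
    # detection: inflection radius per species and sea state
    inflection_radii: dict = field(default_factory=lambda: {
        "porpoise": {0: 2000.0, 1: 1800.0, 2: 1400.0, 3: 1000.0, 4: 800.0},
        "rissos": {0: 2800.0, 1: 2500.0, 2: 2200.0, 3: 1600.0, 4: 1200.0},
    })
    resighting_prob: float = 0.0
    quantize_measurements: bool = True
    max_expected_count: float = 1e6

    @property
    def effect_names(self) -> set[str]:
        names = set()
        for sp_effects in self.effects.values():
            names |= set(sp_effects)
        return names


def default_platforms(projection: TransverseMercator | None = None) -> list[Platform]:
    """Four platforms on the island rim with sector-shaped viewsheds."""
    proj = projection or TransverseMercator()
    local = {
        "A": ((350.0, -440.0), 17.0, (100.0, 210.0)),   # south-east, leeward
        "B": ((-350.0, -440.0), 17.0, (200.0, 310.0)),  # south-west, exposed
        "C": ((-350.0, 440.0), 38.0, (290.0, 40.0)),    # north-west
        "D": ((350.0, 440.0), 60.0, (25.0, 135.0)),     # north-east, sound
    }
    platforms = []
    for pid, ((x, y), h, (s0, s1)) in local.items():
        lon, lat = proj.inverse(x, y)
        platforms.append(Platform(id=pid, lonlat=(lon, lat), height_at_LW=h,
                                  sector_start=s0, sector_end=s1))
    return platforms


def make_tide_table(scenario: SyntheticScenario) -> TideTable:
    """Semidiurnal HW calendar with a 14.77-day spring-neap envelope."""
    if scenario.days < 15:
        raise ValueError("need at least 15 days to contain a neap tide")
    n_hw = int(scenario.days * 24.0 / TIDAL_PERIOD_H) + 2
    t0 = pd.Timestamp(scenario.start) + pd.Timedelta(hours=2)
    times = t0 + pd.to_timedelta(np.arange(n_hw) * TIDAL_PERIOD_H, unit="h")
    phase_d = np.arange(n_hw) * TIDAL_PERIOD_H / 24.0
    heights = (scenario.hw_height_mean
               + scenario.spring_neap_amplitude
               * np.cos(2 * np.pi * phase_d / LUNAR_PERIOD_D))
    return TideTable(pd.DatetimeIndex(times), heights)


def make_bathymetry(scenario: SyntheticScenario) -> RasterGrid:
    """Island nodata mask, west-deep background, shallow east with a gully."""
    xmin, xmax, ymin, ymax = scenario.extent
    if xmax - xmin < 4000 or ymax - ymin < 4000:
        raise ValueError("domain extent must be at least 4x4 km")
    ncols = int(round((xmax - xmin) / scenario.cell_size))
    nrows = int(round((ymax - ymin) / scenario.cell_size))
    grid = RasterGrid(xmin, ymin, scenario.cell_size, np.zeros((nrows, ncols)))
    gx, gy = grid.center_mesh()
    # smooth west(deep)-to-east(shallow) transition across the island axis
    t = 1.0 / (1.0 + np.exp(-gx / 1200.0))
    depth = scenario.west_depth + (scenario.east_depth - scenario.west_depth) * t
    # deterministic smooth roughness (seed-independent topography)
    depth += 1.5 * np.sin(gx / 900.0) * np.cos(gy / 700.0)
    # the gully: a locally deeper channel east of the island
    cx, cy = scenario.gully_center
    sx, sy = scenario.gully_sigma
    depth += scenario.gully_extra_depth * np.exp(
        -0.5 * (((gx - cx) / sx) ** 2 + ((gy - cy) / sy) ** 2))
    # shallowing towards the island rim, then land as nodata
    ax, ay = scenario.island_semi_axes
    rho = np.sqrt((gx / ax) ** 2 + (gy / ay) ** 2)
    rim = np.clip((rho - 1.0) / 0.6, 0.0, 1.0)
    depth = depth * (0.25 + 0.75 * rim)
    depth = np.maximum(depth, 2.0)
    depth[rho <= 1.0] = np.nan
    return grid.copy_with(depth)


def _current_amplitude(scenario: SyntheticScenario,
                       gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Spatial envelope of the tidal stream: strongest in the sound."""
    base = 0.35 * scenario.peak_speed
    sound = 0.65 * scenario.peak_speed * np.exp(
        -0.5 * (((gy - 1400.0) / 900.0) ** 2)) * np.exp(-0.5 * (gx / 2600.0) ** 2)
    west = 0.25 * scenario.peak_speed * np.exp(
        -0.5 * (((gx + 2600.0) / 1500.0) ** 2))
    return base + sound + west


def signed_flow(scenario: SyntheticScenario, tidal_state: float) -> float:
    """Along-axis flow factor in [-1, 1]; positive = flood (toward NW)."""
    return math.sin(2 * math.pi * (tidal_state - scenario.slack_offset_h)
                    / TIDAL_PERIOD_H)


def make_current_cycle(scenario: SyntheticScenario) -> list[CurrentSnapshot]:
    """25 half-hourly snapshots HW-6..HW+6 of a rectilinear regime.

    Flow reverses at the slack states, peaks near HW, and a wake eddy
    spins up west of the island during the flood phase.
    """
    xmin, xmax, ymin, ymax = scenario.extent
    cs = scenario.current_cell_size
    ncols = int(round((xmax - xmin) / cs))
    nrows = int(round((ymax - ymin) / cs))
    template = RasterGrid(xmin, ymin, cs, np.zeros((nrows, ncols)))
    gx, gy = template.center_mesh()
    amp = _current_amplitude(scenario, gx, gy)
    axis = math.radians(scenario.current_axis_deg)
    ux, vy = math.sin(axis), math.cos(axis)
    ex, ey = scenario.eddy_center
    r2 = ((gx - ex) ** 2 + (gy - ey) ** 2) / scenario.eddy_sigma ** 2
    envelope = np.exp(-0.5 * r2)
    snapshots = []
    for ts in np.arange(-6.0, 6.0 + 0.25, 0.5):
        f = signed_flow(scenario, float(ts))
        u = amp * f * ux
        v = amp * f * vy
        if f > 0:  # flood-phase wake eddy west of the island
            swirl = scenario.eddy_strength * f * envelope
            u += -swirl * (gy - ey) / scenario.eddy_sigma
            v += swirl * (gx - ex) / scenario.eddy_sigma
        speed = np.hypot(u, v)
        over = speed > 3.0
        if over.any():
            scalef = np.where(over, 3.0 / speed, 1.0)
            u, v = u * scalef, v * scalef
        snapshots.append(CurrentSnapshot(float(ts),
                                         template.copy_with(u),
                                         template.copy_with(v)))
    return snapshots


def make_effort_schedule(scenario: SyntheticScenario,
                         platforms: list[Platform]) -> pd.DataFrame:
    """10-minute scans per platform with a shared Markov sea-state chain.

    Sea state walks on {0..4}: it persists with the configured
    probability, otherwise steps one Beaufort class up or down (symmetric
    random walk, so the stationary law is uniform).
    """
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    stay = scenario.sea_state_persistence
    rows = []
    state = int(rng.integers(0, 5))
    for day in range(scenario.days):
        day_start = pd.Timestamp(scenario.start) + pd.Timedelta(days=day, hours=8)
        for slot in range(scenario.scans_per_day):
            t = day_start + pd.Timedelta(minutes=10 * slot)
            u = rng.uniform()
            if u > stay:
                step = 1 if u > (1 + stay) / 2 else -1
                state = min(4, max(0, state + step))
            for p in platforms:
                rows.append({"id": f"{p.id}-{day:03d}-{slot:03d}",
                             "platform_id": p.id, "sector": p.id,
                             "start_time": t, "sea_state": state,
                             "visibility": "good"})
    return pd.DataFrame(rows)


def _effect_value(name: str, kind: str, coef: float,
                  scenario: SyntheticScenario, depth, tidal_state):
    if name == "depth" and kind == "linear_std":
        z = (depth - scenario.depth_std_center) / scenario.depth_std_scale
        return coef * z
    if name == "tidal_state" and kind == "cosine":
        return coef * np.cos(2 * np.pi * tidal_state / TIDAL_PERIOD_H)
    if kind == "linear":
        if name == "depth":
            return coef * depth
        raise ValueError(f"unsupported linear effect on {name!r}")
    raise ValueError(f"unsupported effect {name!r}/{kind!r}")




def simulate_dataset(scenario: SyntheticScenario,
                     platforms: list[Platform] | None = None,
                     cfg: GeodeticConfig | None = None):
    """Draw a full synthetic study.

    Returns ``(sightings, scans, env, truth)``: sightings carry quantized
    bearing/reticle measurements plus the true position and distance;
    ``env`` is the built :class:`EnvironmentBundle`; ``truth`` records the
    scenario coefficients and bookkeeping (expected counts, platform set).
    """
    cfg = cfg or GeodeticConfig()
    proj = TransverseMercator()
    platforms = platforms or default_platforms(proj)
    tide = make_tide_table(scenario)
    depth = make_bathymetry(scenario)
    snapshots = make_current_cycle(scenario)
    env = EnvironmentBundle.build(depth, snapshots, tide)
    scans = make_effort_schedule(scenario, platforms)

    species_list = sorted(scenario.effects)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 2]))

    # --- static per-cell intensity factors per platform/species/sea-state
    gx, gy = depth.center_mesh()
    flat_x, flat_y, flat_depth = gx.ravel(), gy.ravel(), depth.values.ravel()
    origins = {p.id: proj.forward(*p.lonlat) for p in platforms}
    static: dict[tuple[str, str, int], tuple[np.ndarray, np.ndarray]] = {}
    cell_area = scenario.cell_size ** 2
    for p in platforms:
        ox, oy = origins[p.id].x, origins[p.id].y
        dx, dy = flat_x - ox, flat_y - oy
        dist = np.hypot(dx, dy)
        bearing = np.degrees(np.arctan2(dx, dy)) % 360.0
        rel = (bearing - p.sector_start) % 360.0
        in_sector = rel <= p.sector_width
        for sp in species_list:
            radii = scenario.inflection_radii[sp]
            for ss in range(5):
                r0 = radii[ss]
                det = np.clip(1.0 - np.maximum(dist - r0, 0.0) / r0, 0.0, 1.0)
                ok = in_sector & (det > 0) & np.isfinite(flat_depth)
                idx = np.nonzero(ok)[0]
                spatial = np.zeros(len(idx))
                for name, (kind, coef) in scenario.effects[sp].items():
                    if name != "tidal_state":
                        spatial += _effect_value(name, kind, coef, scenario,
                                                 flat_depth[idx], None)
                lam = np.exp(scenario.intercepts[sp] + spatial) \
                    * det[idx] * cell_area
                static[(p.id, sp, ss)] = (idx, lam)

    temp = temporal_covariates_frame(scans["start_time"], tide)
    scans = scans.assign(tidal_state=temp["tidal_state"].to_numpy())

    # expected total count guard
    exp_total = 0.0
    for sp in species_list:
        t_eff = sum(coef for n, (kind, coef) in scenario.effects[sp].items()
                    if n == "tidal_state")
        for row in scans.itertuples():
            idx, lam = static[(row.platform_id, sp, row.sea_state)]
            tfac = math.exp(_effect_value(
                "tidal_state", "cosine", t_eff, scenario, None,
                row.tidal_state)) if t_eff else 1.0
            exp_total += lam.sum() * tfac
    if exp_total > scenario.max_expected_count:
        raise ValueError(
            f"expected sighting count {exp_total:.3g} exceeds the "
            f"{scenario.max_expected_count:.0g} cap; lower the intercepts or "
            "shrink the schedule")

    sightings_rows = []
    half = scenario.cell_size / 2.0
    for row in scans.itertuples():
        hw_height = tide.height_above_LW(row.start_time)
        p = next(pp for pp in platforms if pp.id == row.platform_id)
        obs_height = corrected_platform_height(p.height_at_LW,
                                               min(hw_height, p.height_at_LW - 1))
        ox, oy = origins[p.id].x, origins[p.id].y
        for sp in species_list:
            idx, lam = static[(p.id, sp, row.sea_state)]
            temporal = 0.0
            for name, (kind, coef) in scenario.effects[sp].items():
                if name == "tidal_state":
                    temporal += _effect_value(name, kind, coef, scenario,
                                              None, row.tidal_state)
            lam_total = float(lam.sum() * math.exp(temporal))
            n = rng.poisson(lam_total)
            if n == 0:
                continue
            cells = rng.choice(idx, size=n, p=lam / lam.sum())
            px = flat_x[cells] + rng.uniform(-half, half, n)
            py = flat_y[cells] + rng.uniform(-half, half, n)
            for xx, yy in zip(px, py):
                d = math.hypot(xx - ox, yy - oy)
                bearing = math.degrees(math.atan2(xx - ox, yy - oy)) % 360.0
                ret = distance_to_reticles(d, obs_height, cfg)
                if scenario.quantize_measurements:
                    bearing = float(round(bearing) % 360)
                    ret = round(ret * 2) / 2.0
                rec = {"scan_id": row.id, "species": sp,
                       "bearing": bearing, "reticles": ret,
                       "group_size": 1 + int(rng.poisson(0.6)),
                       "calves": 0,
                       "surfacing_speed": "moderate",
                       "true_x": xx, "true_y": yy, "true_distance": d}
                sightings_rows.append(rec)
                if rng.uniform() < scenario.resighting_prob:
                    sightings_rows.append(dict(rec))
    sightings = pd.DataFrame(sightings_rows)
    truth = {
        "seed": scenario.seed,
        "intercepts": dict(scenario.intercepts),
        "effects": {sp: dict(v) for sp, v in scenario.effects.items()},
        "depth_std_center": scenario.depth_std_center,
        "depth_std_scale": scenario.depth_std_scale,
        "inflection_radii": {sp: dict(v)
                             for sp, v in scenario.inflection_radii.items()},
        "expected_sightings": exp_total,
        "platforms": {p.id: {"height_at_LW": p.height_at_LW,
                             "sector": (p.sector_start, p.sector_end)}
                      for p in platforms},
    }
    return sightings, scans.drop(columns=["tidal_state"]), env, truth
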