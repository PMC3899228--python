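"""Staged analysis pipeline.

Library-level glue between the survey tables and the model modules:
geolocating whole sighting logs, building the species-specific
use-availability designs, sector geometry and survey areas, effort
summaries, and a stage runner (`simulate`, `geolocate`, `detect`,
`covariates`, `kde`, `fit`, `select`, `report`) that writes each stage's
outputs together with a JSON manifest (config snapshot, seed, input
hashes) so reruns are reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import Polygon
from shapely.ops import unary_union

from . import io as swio
from .covariates import EnvironmentBundle, TideTable, sample_covariates_frame
from .detection import (DetectionLimits, accumulation_curve,
                        apply_detection_filter, estimate_inflection,
                        DEFAULT_SPECIES_RULES)
from .geolocation import (GeodeticConfig, Platform, TransverseMercator,
                          corrected_platform_height,
                          quantized_detection_radius, reticle_to_distance)
from .ipp_model import fit_iwlr, forward_select
from .kde import (balance_effort, contours_to_geojson, core_area_percentage,
                  kde_surface, scv_bandwidth, volume_contours,
                  weight_overlap_sightings)
from .raster import read_ascii_grid, write_ascii_grid
from .smooths import SmoothTermSpec
from .synthetic import SyntheticScenario, simulate_dataset, default_platforms

__all__ = [
    "geolocate_sightings",
    "sector_wedge",
    "survey_area_km2",
    "build_use_availability",
    "effort_summary",
    "PipelineConfig",
    "run_stage",
    "STAGES",
]

STAGES = ("simulate", "geolocate", "detect", "covariates", "kde",
          "fit", "select", "report")


# ---------------------------------------------------------------------------
# analysis glue

def geolocate_sightings(sightings: pd.DataFrame, scans: pd.DataFrame,
                        platforms: list[Platform], tide: TideTable,
                        cfg: GeodeticConfig | None = None,
                        projection: TransverseMercator | None = None
                        ) -> pd.DataFrame:
    """Convert bearing/reticle observations to local x/y positions.

    Adds ``x, y, distance_m, observer_height_m, in_sector`` columns; the
    observer height is the platform height at low water minus the tidal
    height at scan time.
    """
    cfg = cfg or GeodeticConfig()
    proj = projection or TransverseMercator()
    pmap = {p.id: p for p in platforms}
    origins = {p.id: proj.forward(*p.lonlat) for p in platforms}
    scan_info = scans.rename(columns={"id": "scan_id"}).set_index("scan_id")
    xs, ys, dists, heights, flags = [], [], [], [], []
    for row in sightings.itertuples():
        scan = scan_info.loc[row.scan_id]
        platform = pmap[scan["platform_id"]]
        tidal = min(tide.height_above_LW(scan["start_time"]),
                    platform.height_at_LW - 1.0)
        h = corrected_platform_height(platform.height_at_LW, max(tidal, 0.0))
        d = reticle_to_distance(h, row.reticles, cfg)
        o = origins[platform.id]
        b = math.radians(row.bearing)
        xs.append(o.x + d * math.sin(b))
        ys.append(o.y + d * math.cos(b))
        dists.append(d)
        heights.append(h)
        flags.append(platform.bearing_in_sector(row.bearing, tolerance=2.0))
    out = sightings.copy()
    out["x"], out["y"], out["distance_m"] = xs, ys, dists
    out["observer_height_m"], out["in_sector"] = heights, flags
    return out


def sector_wedge(platform: Platform, radius: float,
                 origin_xy: tuple[float, float],
                 n_arc: int = 64) -> Polygon:
    """Shapely polygon of a platform's viewshed clipped to ``radius``."""
    ox, oy = origin_xy
    width = platform.sector_width
    angles = np.radians(platform.sector_start
                        + np.linspace(0.0, width, n_arc))
    pts = [(ox, oy)] + [(ox + radius * math.sin(a), oy + radius * math.cos(a))
                        for a in angles]
    return Polygon(pts)


def sector_geometries(platforms: list[Platform], radii: dict[str, float],
                      projection: TransverseMercator | None = None
                      ) -> dict[str, Polygon]:
    proj = projection or TransverseMercator()
    out = {}
    for p in platforms:
        o = proj.forward(*p.lonlat)
        out[p.id] = sector_wedge(p, radii[p.id], (o.x, o.y))
    return out


def survey_area_km2(platforms: list[Platform], limits: DetectionLimits,
                    species: str,
                    projection: TransverseMercator | None = None) -> float:
    """Union of sector wedges clipped to the sea-state-0 inflection radii."""
    radii = {p.id: limits.radius(p.id, species, 0) for p in platforms}
    wedges = sector_geometries(platforms, radii, projection)
    return unary_union(list(wedges.values())).area / 1e6


def build_use_availability(filtered: pd.DataFrame, scans: pd.DataFrame,
                           platforms: list[Platform], limits: DetectionLimits,
                           env: EnvironmentBundle, species: str,
                           n_per_scan: int = 2, seed: int = 0,
                           W: float = 1000.0,
                           species_rules: dict[str, int] | None = None,
                           projection: TransverseMercator | None = None,
                           align_to_reticle_rings: bool = True,
                           cfg: GeodeticConfig | None = None
                           ) -> pd.DataFrame:
    """Assemble the IWLR design for one species.

    Presences are the filtered, geolocated sightings (response 1, weight
    1). For every scan within the species' sea-state cap, ``n_per_scan``
    availability points are drawn uniformly by area over the sector wedge
    up to that stratum's inflection radius (response 0). Because the
    wedge area varies with the sea-state-specific radius while the point
    count per scan is fixed, each availability point carries a quadrature
    case weight proportional to its scan's wedge area (scaled to average
    ``W``), so the availability sample represents a uniform measure over
    the realised effort. Covariates are sampled for both; rows hitting
    nodata covariates are redrawn (availability) or dropped with a count
    in ``attrs``.

    With ``align_to_reticle_rings`` the per-scan radius is the effective
    boundary of the half-reticle-rounded detection region (see
    :func:`shorewatch.geolocation.quantized_detection_radius`): distances
    are measured on discrete reticle rings, so the region a distance
    filter actually admits ends midway between rings and breathes with
    the tide through the observer height. Matching the availability
    region to it removes a tide-correlated bias in temporal effects.
    """
    rules = DEFAULT_SPECIES_RULES if species_rules is None else species_rules
    proj = projection or TransverseMercator()
    pmap = {p.id: p for p in platforms}
    origins = {p.id: proj.forward(*p.lonlat) for p in platforms}
    rng = np.random.default_rng(seed)

    scans = scans[scans["sea_state"] <= rules[species]].copy()
    scan_info = scans.rename(columns={"id": "scan_id"}).set_index("scan_id")

    # presences
    pres = filtered[filtered["species"] == species].copy()
    pres = pres.join(scan_info[["platform_id", "start_time", "sea_state"]],
                     on="scan_id")
    use_cov = sample_covariates_frame(
        pres["x"].to_numpy(), pres["y"].to_numpy(),
        pres["start_time"], env)
    use = use_cov.assign(response=1, scan_id=pres["scan_id"].to_numpy(),
                         site=pres["platform_id"].to_numpy(),
                         sea_state=pres["sea_state"].to_numpy(),
                         case_weight=1.0)
    n_dropped = int((~use["valid"]).sum())
    use = use[use["valid"]]

    # availability: vectorised wedge sampling with redraws on nodata
    rep = scans.loc[scans.index.repeat(n_per_scan)].reset_index(drop=True)
    pids = rep["platform_id"].to_numpy()
    starts = np.array([pmap[p].sector_start for p in pids])
    widths = np.array([pmap[p].sector_width for p in pids])
    ox = np.array([origins[p].x for p in pids])
    oy = np.array([origins[p].y for p in pids])
    radii = np.array([limits.radius(p, species, s)
                      for p, s in zip(pids, rep["sea_state"])])
    if align_to_reticle_rings:
        gcfg = cfg or GeodeticConfig()
        heights = np.array([
            corrected_platform_height(
                pmap[p].height_at_LW,
                max(min(env.tide.height_above_LW(t),
                        pmap[p].height_at_LW - 1.0), 0.0))
            for p, t in zip(pids, rep["start_time"])])
        radii = np.array([quantized_detection_radius(r0, h, gcfg)
                          for r0, h in zip(radii, heights)])

    def draw(mask):
        theta = np.radians(starts[mask] + rng.uniform(size=mask.sum()) * widths[mask])
        r = radii[mask] * np.sqrt(rng.uniform(size=mask.sum()))
        return ox[mask] + r * np.sin(theta), oy[mask] + r * np.cos(theta)

    n = len(rep)
    ax = np.empty(n)
    ay = np.empty(n)
    pending = np.ones(n, dtype=bool)
    avail_cov = None
    for _ in range(100):
        if not pending.any():
            break
        ax[pending], ay[pending] = draw(pending)
        cov = sample_covariates_frame(ax, ay, rep["start_time"], env)
        pending = ~cov["valid"].to_numpy()
        avail_cov = cov
    if pending.any():
        raise RuntimeError(
            f"{pending.sum()} availability points still on nodata after "
            "100 redraw rounds")
    wedge_area = (widths / 360.0) * np.pi * radii ** 2
    quad_weight = W * wedge_area / wedge_area.mean()
    avail = avail_cov.assign(response=0, scan_id=rep["id"].to_numpy(),
                             site=rep["platform_id"].to_numpy(),
                             sea_state=rep["sea_state"].to_numpy(),
                             case_weight=quad_weight)
    records = pd.concat([use, avail], ignore_index=True)
    records["day_id"] = pd.to_datetime(
        records["scan_id"].map(scan_info["start_time"])).dt.strftime("%Y-%m-%d")
    records.attrs["n_dropped_nodata"] = n_dropped
    records.attrs["species"] = species
    return records.drop(columns=["valid"])


def effort_summary(scans: pd.DataFrame, sightings: pd.DataFrame) -> pd.DataFrame:
    """Per-site effort and sighting bookkeeping with a totals row.

    Columns mirror the survey-overview layout: scans, sightings (and
    animal counts) per species, and scans per calendar month.
    """
    scans = scans.copy()
    scans["month"] = pd.to_datetime(scans["start_time"]).dt.strftime("%B")
    merged = sightings.merge(
        scans.rename(columns={"id": "scan_id"})[["scan_id", "platform_id"]],
        on="scan_id", how="left")
    rows = []
    for site, grp in scans.groupby("platform_id"):
        srow = {"site": site, "scans": len(grp)}
        for sp in ("porpoise", "rissos"):
            sub = merged[(merged["platform_id"] == site)
                         & (merged["species"] == sp)]
            srow[f"{sp}_sightings"] = len(sub)
            srow[f"{sp}_animals"] = int(sub["group_size"].sum()) \
                if "group_size" in sub.columns else len(sub)
        for month in sorted(grp["month"].unique()):
            srow[f"scans_{month}"] = int((grp["month"] == month).sum())
        rows.append(srow)
    df = pd.DataFrame(rows).fillna(0)
    total = {"site": "TOTAL"}
    for c in df.columns:
        if c != "site":
            total[c] = df[c].sum()
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


# ---------------------------------------------------------------------------
# stage runner

_KNOWN_KEYS = {
    "seed", "out_dir", "scenario", "geodetic", "detection", "kde", "model",
    "inputs",
}


class PipelineConfig(dict):
    """Validated pipeline configuration (unknown top-level keys rejected)."""

    def __init__(self, mapping: dict):
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        super().__init__(mapping)
        self.setdefault("seed", 0)
        self.setdefault("out_dir", "pipeline_out")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, config: dict,
                    inputs: list[Path], outputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "seed": config.get("seed", 0),
        "config": {k: v for k, v in config.items()},
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
        "outputs": [str(p) for p in outputs],
    }
    (out / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2,
                                                           default=str))


def _load_environment(out: Path) -> tuple:
    depth = read_ascii_grid(out / "depth.asc")
    snapshots = swio.read_current_snapshots(out / "currents" / "currents.yaml")
    tide = TideTable.from_csv(out / "tide.csv")
    platforms = swio.read_platforms(out / "platforms.yaml")
    return depth, snapshots, tide, platforms


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream output {path.name}; run the {producer!r} "
            "stage first")
    return path


def run_stage(name: str, config: PipelineConfig) -> dict:
    """Execute one pipeline stage; returns a summary dict."""
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    if name == "simulate":
        sc_over = config.get("scenario") or {}
        scenario = SyntheticScenario(seed=seed, **sc_over)
        sightings, scans, env, truth = simulate_dataset(scenario)
        platforms = default_platforms()
        swio.write_scans(scans, out / "scans.csv")
        swio.write_sightings(sightings, out / "sightings.csv")
        write_ascii_grid(env.depth, out / "depth.asc")
        swio.write_current_snapshots(env.snapshots, out / "currents")
        env.tide.to_csv(out / "tide.csv")
        swio.write_platforms(platforms, out / "platforms.yaml")
        (out / "truth.json").write_text(json.dumps(truth, indent=2, default=str))
        outputs = [out / f for f in ("scans.csv", "sightings.csv", "depth.asc",
                                     "tide.csv", "platforms.yaml", "truth.json")]
        _write_manifest(out, name, config, [], outputs)
        return {"n_scans": len(scans), "n_sightings": len(sightings)}

    if name == "geolocate":
        scans = swio.read_scans(_require(out / "scans.csv", "simulate"))
        sightings = swio.read_sightings(_require(out / "sightings.csv", "simulate"))
        depth, snaps, tide, platforms = _load_environment(out)
        geo = geolocate_sightings(sightings, scans, platforms, tide)
        geo.to_csv(out / "sightings_geo.csv", index=False)
        _write_manifest(out, name, config,
                        [out / "scans.csv", out / "sightings.csv"],
                        [out / "sightings_geo.csv"])
        return {"n_geolocated": len(geo)}

    if name == "detect":
        scans = swio.read_scans(_require(out / "scans.csv", "simulate"))
        geo = pd.read_csv(_require(out / "sightings_geo.csv", "geolocate"))
        det_cfg = config.get("detection") or {}
        min_points = int(det_cfg.get("min_points", 20))
        merged = geo.merge(scans.rename(columns={"id": "scan_id"})
                           [["scan_id", "platform_id", "sea_state"]],
                           on="scan_id")
        limits = {}
        for (site, sp, ss), grp in merged.groupby(
                ["platform_id", "species", "sea_state"]):
            if len(grp) >= min_points:
                est = estimate_inflection(
                    accumulation_curve(grp["distance_m"], key=(site, sp, ss)),
                    min_points=min_points)
                limits[(site, sp, int(ss))] = est.radius
        # strata too sparse to estimate fall back to the site/species curve,
        # then to the species curve pooled over sites, so every stratum in
        # play has a radius
        for (site, sp), grp in merged.groupby(["platform_id", "species"]):
            if len(grp) < min_points:
                continue
            est = estimate_inflection(
                accumulation_curve(grp["distance_m"], key=(site, sp)),
                min_points=min_points)
            for ss in range(5):
                limits.setdefault((site, sp, ss), est.radius)
        all_sites = scans["platform_id"].unique()
        for sp, grp in merged.groupby("species"):
            if len(grp) < min_points:
                continue
            est = estimate_inflection(
                accumulation_curve(grp["distance_m"], key=(sp,)),
                min_points=min_points)
            for site in all_sites:
                for ss in range(5):
                    limits.setdefault((site, sp, ss), est.radius)
        dl = DetectionLimits(limits)
        dl.to_csv(out / "detection_limits.csv")
        filtered = apply_detection_filter(geo, scans, dl)
        filtered.to_csv(out / "sightings_filtered.csv", index=False)
        _write_manifest(out, name, config, [out / "sightings_geo.csv"],
                        [out / "detection_limits.csv",
                         out / "sightings_filtered.csv"])
        return {"n_filtered": len(filtered), "n_limits": len(limits)}

    if name == "covariates":
        depth, snaps, tide, platforms = _load_environment(out)
        env = EnvironmentBundle.build(depth, snaps, tide)
        outputs = []
        for label, grid in (("slope", env.slope), ("sd_slope", env.sd_slope),
                            ("aspect", env.aspect),
                            ("sd_current_speed", env.sd_current_speed),
                            ("mean_stratification", env.mean_strat)):
            path = out / f"{label}.asc"
            write_ascii_grid(grid, path)
            outputs.append(path)
        _write_manifest(out, name, config, [out / "depth.asc"], outputs)
        return {"surfaces": [p.name for p in outputs]}

    if name == "kde":
        scans = swio.read_scans(_require(out / "scans.csv", "simulate"))
        filtered = pd.read_csv(_require(out / "sightings_filtered.csv", "detect"))
        depth, snaps, tide, platforms = _load_environment(out)
        kde_cfg = config.get("kde") or {}
        n_per_sector = int(kde_cfg.get("n_per_sector", 600))
        levels = kde_cfg.get("levels", [50, 60, 75, 95])
        sub_scans, sub_sight = balance_effort(scans, filtered,
                                              n_per_sector=n_per_sector,
                                              seed=seed)
        limits = DetectionLimits.from_csv(out / "detection_limits.csv")
        summary = {}
        outputs = []
        for sp, grp in sub_sight.groupby("species"):
            radii = {p.id: max(limits.limits.get((p.id, sp, ss), 0.0)
                               for ss in range(3)) or 2000.0
                     for p in platforms}
            geoms = sector_geometries(platforms, radii)
            pts, orphan = weight_overlap_sightings(
                grp[["x", "y"]].to_numpy(), geoms)
            H, meta = scv_bandwidth(pts)
            surface = kde_surface(pts, H, grid=depth)
            contours = volume_contours(surface, levels=levels)
            write_ascii_grid(surface.grid, out / f"kde_{sp}.asc")
            contours_to_geojson(contours, out / f"contours_{sp}.geojson",
                                species=sp)
            outputs += [out / f"kde_{sp}.asc", out / f"contours_{sp}.geojson"]
            summary[sp] = {
                "n_points": pts.n, "bandwidth_method": meta["method"],
                "areas_km2": {c.level: c.area_km2 for c in contours}}
        (out / "kde_summary.json").write_text(json.dumps(summary, indent=2))
        _write_manifest(out, name, config,
                        [out / "sightings_filtered.csv"], outputs)
        return summary

    if name in ("fit", "select"):
        scans = swio.read_scans(_require(out / "scans.csv", "simulate"))
        filtered = pd.read_csv(_require(out / "sightings_filtered.csv", "detect"))
        depth, snaps, tide, platforms = _load_environment(out)
        env = EnvironmentBundle.build(depth, snaps, tide)
        limits = DetectionLimits.from_csv(out / "detection_limits.csv")
        model_cfg = config.get("model") or {}
        W = float(model_cfg.get("W", 1000.0))
        species = model_cfg.get("species", "porpoise")
        records = build_use_availability(filtered, scans, platforms, limits,
                                         env, species, seed=seed, W=W)
        records.to_csv(out / f"records_{species}.csv", index=False)
        term_names = model_cfg.get(
            "terms", ["depth", "slope", "tidal_state", "lunar_cycle"])
        terms = [SmoothTermSpec.smooth(t) for t in term_names]
        if name == "fit":
            model = fit_iwlr(records, terms, W=W)
            summary = {
                "species": species,
                "deviance_explained": model.deviance_explained,
                "edf": model.edf,
                "lambdas": model.lambdas,
                "coefficients": model.coefficient_table().to_dict("records"),
            }
            (out / f"model_{species}.json").write_text(
                json.dumps(summary, indent=2))
            _write_manifest(out, name, config, [out / "sightings_filtered.csv"],
                            [out / f"model_{species}.json"])
            return {"deviance_explained": model.deviance_explained}
        table, model = forward_select(terms, records, W=W)
        table.to_csv(out / f"selection_{species}.csv", index=False)
        _write_manifest(out, name, config, [out / f"records_{species}.csv"],
                        [out / f"selection_{species}.csv"])
        return {"n_retained": int(table["retained"].sum())}

    # report
    scans = swio.read_scans(_require(out / "scans.csv", "simulate"))
    sightings = pd.read_csv(_require(out / "sightings_filtered.csv", "detect"))
    summary = effort_summary(scans, sightings)
    summary.to_csv(out / "effort_summary.csv", index=False)
    lines = ["Survey effort and sightings", summary.to_string(index=False), ""]
    kde_path = out / "kde_summary.json"
    if kde_path.exists():
        kde_summary = json.loads(kde_path.read_text())
        limits = DetectionLimits.from_csv(out / "detection_limits.csv")
        platforms = swio.read_platforms(out / "platforms.yaml")
        for sp, info in kde_summary.items():
            try:
                area = survey_area_km2(platforms, limits, sp)
            except KeyError:
                continue
            core = info["areas_km2"].get("50")
            if core is not None:
                pct = core_area_percentage(core, area)
                lines.append(
                    f"{sp}: 50% core area {core:.2f} km2 = {pct}% of the "
                    f"{area:.2f} km2 survey area")
    for sp in ("porpoise", "rissos"):
        model_path = out / f"model_{sp}.json"
        if model_path.exists():
            m = json.loads(model_path.read_text())
            lines.append(f"{sp}: deviance explained "
                         f"{m['deviance_explained']:.1f}%")
    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    _write_manifest(out, "report", config, [out / "effort_summary.csv"],
                    [out / "report.txt"])
    return {"report": str(out / "report.txt")}
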