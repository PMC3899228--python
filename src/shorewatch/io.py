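"""Readers and writers for the survey file formats.

Everything is plain text: scans and sightings as CSV with ISO-8601
timestamps, platforms as a YAML block, detection limits as CSV, tide
tables as CSV, rasters as ESRI ASCII grids, and current snapshots as one
u/v grid pair per tidal state listed in a YAML manifest.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .covariates import CurrentSnapshot
from .geolocation import Platform
from .raster import read_ascii_grid, write_ascii_grid

__all__ = [
    "write_scans", "read_scans",
    "write_sightings", "read_sightings",
    "write_platforms", "read_platforms",
    "write_current_snapshots", "read_current_snapshots",
]


def write_scans(scans: pd.DataFrame, path: str | Path) -> None:
    out = scans.copy()
    out["start_time"] = pd.to_datetime(out["start_time"]).dt.strftime(
        "%Y-%m-%dT%H:%M:%S")
    out.to_csv(path, index=False)


def read_scans(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["start_time"])
    df["sea_state"] = df["sea_state"].astype(int)
    return df


def write_sightings(sightings: pd.DataFrame, path: str | Path) -> None:
    sightings.to_csv(path, index=False)


def read_sightings(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_platforms(platforms: list[Platform], path: str | Path) -> None:
    block = {
        "platforms": [
            {"id": p.id, "lon": float(p.lonlat[0]), "lat": float(p.lonlat[1]),
             "height_at_LW": float(p.height_at_LW),
             "sector_start": float(p.sector_start),
             "sector_end": float(p.sector_end)}
            for p in platforms
        ]
    }
    Path(path).write_text(yaml.safe_dump(block, sort_keys=False))


def read_platforms(path: str | Path) -> list[Platform]:
    block = yaml.safe_load(Path(path).read_text())
    return [Platform(id=str(d["id"]), lonlat=(d["lon"], d["lat"]),
                     height_at_LW=d["height_at_LW"],
                     sector_start=d["sector_start"],
                     sector_end=d["sector_end"])
            for d in block["platforms"]]


def write_current_snapshots(snapshots: list[CurrentSnapshot],
                            directory: str | Path) -> Path:
    """One .asc pair per tidal state plus a YAML manifest; returns it."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for snap in snapshots:
        tag = f"{snap.tidal_state:+05.1f}h".replace("+", "p").replace("-", "m")
        u_name, v_name = f"u_{tag}.asc", f"v_{tag}.asc"
        write_ascii_grid(snap.u, directory / u_name)
        write_ascii_grid(snap.v, directory / v_name)
        entries.append({"tidal_state": float(snap.tidal_state),
                        "u": u_name, "v": v_name})
    manifest = directory / "currents.yaml"
    manifest.write_text(yaml.safe_dump({"snapshots": entries}, sort_keys=False))
    return manifest


def read_current_snapshots(manifest: str | Path) -> list[CurrentSnapshot]:
    manifest = Path(manifest)
    block = yaml.safe_load(manifest.read_text())
    out = []
    for e in block["snapshots"]:
        out.append(CurrentSnapshot(
            float(e["tidal_state"]),
            read_ascii_grid(manifest.parent / e["u"]),
            read_ascii_grid(manifest.parent / e["v"])))
    return out
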