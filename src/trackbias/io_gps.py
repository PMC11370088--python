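"""Reading and writing logger fix tables and derived products.

The canonical in-memory representation of a sequence of GPS fixes is a
pandas DataFrame with columns

    t            -- UTC epoch seconds (float, 1 s resolution native)
    lat, lon     -- WGS84 decimal degrees
    point_speed  -- Doppler-derived instantaneous ground speed, m/s (may be NaN)

wrapped in a :class:`RawPath` carrying per-deployment metadata.  Units are
metres / seconds / m-per-s throughout the package; km/h appears only at
ingestion (declared unit) and in reports.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

FIX_COLUMNS = ["t", "lat", "lon", "point_speed"]

KMH_TO_MS = 1.0 / 3.6


@dataclass
class RawPath:
    """One logger deployment: an ordered table of fixes plus metadata."""

    bird_id: str
    fixes: pd.DataFrame
    species: str = ""
    nominal_interval: float = 1.0

    def __post_init__(self):
        if self.nominal_interval not in (1, 2, 1.0, 2.0):
            raise ValueError("nominal_interval must be 1 or 2 seconds")
        if len(self.fixes) == 0:
            raise ValueError(f"path {self.bird_id!r} has no fixes")

    def __len__(self) -> int:
        return len(self.fixes)

    def copy_with(self, fixes: pd.DataFrame) -> "RawPath":
        return RawPath(
            bird_id=self.bird_id,
            fixes=fixes.reset_index(drop=True),
            species=self.species,
            nominal_interval=self.nominal_interval,
        )


@dataclass
class IngestReport:
    """Counts of rows dropped during ingestion, by reason."""

    n_input: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=dict)


def _validate_fixes(df: pd.DataFrame, where: str = "") -> None:
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise ValueError(f"coordinates out of bounds {where}")
    sp = df["point_speed"].dropna()
    if (sp < 0).any():
        raise ValueError(f"negative point speed {where}")


def read_fix_table(
    path,
    column_map=None,
    tz: str = "UTC",
    speed_unit: str = "m/s",
    delimiter: str = ",",
    bird_id: str | None = None,
    species: str = "",
    nominal_interval: float = 1.0,
):
    """Read a delimited logger export into a :class:`RawPath`.

    Parameters
    ----------
    column_map
        Mapping from canonical names (``timestamp``, ``lat``, ``lon``,
        ``point_speed``) to the column names in the file.  Identity by
        default.  ``point_speed`` is optional; the others are mandatory.
    tz
        Timezone of the timestamps in the file (IANA id); converted to UTC.
    speed_unit
        ``"m/s"`` or ``"km/h"``; speeds are converted to m/s internally.
    delimiter
        Field delimiter (i-gotU / CatTraQ exports vary).

    Returns
    -------
    (RawPath, IngestReport)
        Rows with unparseable timestamps or coordinates are dropped and
        counted in the report; ingestion never reorders surviving rows.
    """
    if speed_unit not in ("m/s", "km/h"):
        raise ValueError(f"unknown speed unit {speed_unit!r}")
    raw = pd.read_csv(path, delimiter=delimiter)
    if len(raw) == 0:
        raise ValueError(f"empty fix table: {path}")
    cmap = {"timestamp": "timestamp", "lat": "lat", "lon": "lon",
            "point_speed": "point_speed"}
    cmap.update(column_map or {})
    for key in ("timestamp", "lat", "lon"):
        if cmap[key] not in raw.columns:
            raise ValueError(
                f"mandatory column {cmap[key]!r} (for {key}) missing from {path}"
            )
    report = IngestReport(n_input=len(raw))

    ts = pd.to_datetime(raw[cmap["timestamp"]], errors="coerce", utc=False)
    if ts.dt.tz is None:
        ts = ts.dt.tz_localize(tz, nonexistent="NaT", ambiguous="NaT")
    ts = ts.dt.tz_convert("UTC")
    lat = pd.to_numeric(raw[cmap["lat"]], errors="coerce")
    lon = pd.to_numeric(raw[cmap["lon"]], errors="coerce")
    if cmap["point_speed"] in raw.columns:
        speed = pd.to_numeric(raw[cmap["point_speed"]], errors="coerce")
        if speed_unit == "km/h":
            speed = speed * KMH_TO_MS
    else:
        speed = pd.Series(np.nan, index=raw.index)

    bad_ts = ts.isna()
    bad_coord = lat.isna() | lon.isna() | (lat.abs() > 90) | (lon.abs() > 180)
    keep = ~(bad_ts | bad_coord)
    report.dropped["unparseable_timestamp"] = int(bad_ts.sum())
    report.dropped["unparseable_coordinates"] = int((bad_coord & ~bad_ts).sum())
    report.n_kept = int(keep.sum())
    if report.n_kept == 0:
        raise ValueError(f"no valid fixes in {path}")

    df = pd.DataFrame(
        {
            "t": ts[keep].astype("int64").to_numpy() / 1e9,
            "lat": lat[keep].to_numpy(float),
            "lon": lon[keep].to_numpy(float),
            "point_speed": speed[keep].to_numpy(float),
        }
    )
    _validate_fixes(df, where=str(path))
    path_obj = RawPath(
        bird_id=bird_id or os.path.splitext(os.path.basename(str(path)))[0],
        fixes=df,
        species=species,
        nominal_interval=nominal_interval,
    )
    return path_obj, report


def flight_to_geojson_feature(flight) -> dict:
    """One flight as a GeoJSON LineString feature (lon, lat order)."""
    coords = [
        [float(lo), float(la)]
        for lo, la in zip(flight.fixes["lon"], flight.fixes["lat"])
    ]
    props = {
        "flight_id": flight.flight_id,
        "bird_id": flight.bird_id,
        "si": None if flight.si is None or math.isnan(flight.si) else float(flight.si),
        "flight_class": flight.flight_class,
        "duration_s": float(flight.duration),
        "t_start": float(flight.fixes["t"].iloc[0]),
        "nominal_interval": float(flight.nominal_interval),
    }
    return {
        "type": "Feature",
        "geometry": {"type": "LineString", "coordinates": coords},
        "properties": props,
    }


def write_flights_geojson(flights, out_file) -> int:
    fc = {
        "type": "FeatureCollection",
        "features": [flight_to_geojson_feature(f) for f in flights],
    }
    with open(out_file, "w") as fh:
        json.dump(fc, fh)
    return len(fc["features"])


def read_flights_geojson(in_file):
    """Inverse of :func:`write_flights_geojson` (timestamps reconstructed
    from t_start at the stored nominal interval)."""
    from .preprocess import Flight  # local import to avoid a cycle

    with open(in_file) as fh:
        fc = json.load(fh)
    flights = []
    for feat in fc["features"]:
        props = feat["properties"]
        coords = np.asarray(feat["geometry"]["coordinates"], dtype=float)
        dt = props.get("nominal_interval", 1.0)
        t0 = props.get("t_start", 0.0)
        df = pd.DataFrame(
            {
                "t": t0 + dt * np.arange(len(coords)),
                "lat": coords[:, 1],
                "lon": coords[:, 0],
                "point_speed": np.nan,
            }
        )
        flights.append(
            Flight(
                flight_id=props["flight_id"],
                bird_id=props["bird_id"],
                fixes=df,
                nominal_interval=dt,
                si=props.get("si"),
                flight_class=props.get("flight_class"),
            )
        )
    return flights


def write_products(out_dir, flights=None, tables=None) -> dict:
    """Write derived products and return a manifest.

    ``flights`` go to ``flights.geojson``; ``tables`` is a mapping
    ``name -> DataFrame`` written as ``<name>.csv``.  The manifest (also
    written as ``manifest.json``) lists every file with its record count.
    """
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")
    manifest = {"files": []}
    if flights is not None:
        f = os.path.join(out_dir, "flights.geojson")
        n = write_flights_geojson(flights, f)
        manifest["files"].append({"file": "flights.geojson", "rows": n})
    for name, table in (tables or {}).items():
        fname = f"{name}.csv"
        table.to_csv(os.path.join(out_dir, fname), index=False)
        manifest["files"].append({"file": fname, "rows": int(len(table))})
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
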