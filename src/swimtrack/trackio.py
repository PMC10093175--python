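"""Readers and writers for on-disk artifacts.

Formats:

* fix tables — UTF-8 CSV, one row per satellite fix, ISO-8601 UTC
  timestamps, columns ``animal_id,time,lon,lat,smaj_km,smin_km,eor_deg,
  qclass`` (error-ellipse axes in km; an optional ``unit`` column value
  of ``m`` marks metre-valued axes, converted on read);
* gridded fields — CF-style NetCDF (written through xarray's scipy
  backend) with regular lon/lat axes and a daily time axis (weekly for
  the sargassum variable);
* daily products — one tidy CSV joining positions, velocity
  decompositions and environmental annotations, plus GeoJSON
  FeatureCollections of LineStrings per animal;
* summary tables — TSV.

No reader mutates values beyond the documented normalizations (sorting
by time within animal, collapsing duplicate timestamps to the first
occurrence, wrapping longitudes to [-180, 180)).
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import xarray as xr

from .geodesy import wrap_lon

FIX_COLUMNS = ["animal_id", "time", "lon", "lat", "smaj_km", "smin_km", "eor_deg", "qclass"]
_MANDATORY = ["animal_id", "time", "lon", "lat"]


class SchemaError(ValueError):
    pass


def write_fixes(fixes: pd.DataFrame, path):
    df = fixes.copy()
    df["time"] = pd.to_datetime(df["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    df.to_csv(path, index=False, float_format="%.10g")


def read_fixes(path) -> pd.DataFrame:
    """Read a fix table; sort by time within animal, collapse duplicate stamps.

    Returns an empty, correctly typed frame for an empty file.  Raises
    SchemaError naming the missing column, or ValueError listing the row
    of the first unparseable timestamp.
    """
    try:
        df = pd.read_csv(path, dtype={"animal_id": str, "qclass": str})
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=FIX_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=FIX_COLUMNS)
    for col in _MANDATORY:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    t = pd.to_datetime(df["time"], format="ISO8601", errors="coerce")
    if t.isna().any():
        bad = int(np.flatnonzero(t.isna())[0]) + 2  # header is line 1
        raise ValueError(f"unparseable timestamp at line {bad} of {path}")
    df["time"] = t
    if "unit" in df.columns:
        metres = df["unit"].astype(str).str.lower() == "m"
        for col in ("smaj_km", "smin_km"):
            if col in df.columns:
                df[col] = df[col].astype(float)
                df.loc[metres, col] = df.loc[metres, col] / 1000.0
        df = df.drop(columns=["unit"])
    df["lon"] = wrap_lon(df["lon"].to_numpy(dtype=float))
    df = df.sort_values(["animal_id", "time"], kind="stable")
    df = df.drop_duplicates(subset=["animal_id", "time"], keep="first")
    return df.reset_index(drop=True)


def write_field(dataset: xr.Dataset, path):
    """Write a gridded field as CF-style NetCDF (classic format)."""
    enc = {}
    for name in dataset.data_vars:
        enc[name] = {"dtype": "float32"}
    dataset.to_netcdf(path, engine="scipy", encoding=enc)


def read_field(path) -> xr.Dataset:
    """Read a gridded field; validate axis regularity, normalize longitudes.

    Longitude axes stored 0-360 are shifted to [-180, 180) (with the data
    rolled accordingly).  Irregular axes raise a format error; a gap in
    the daily time axis raises an error naming the first missing date.
    """
    ds = xr.load_dataset(path, engine="scipy", decode_timedelta=False)
    lon = ds["lon"].values
    if lon.max() > 180.0:
        ds = ds.assign_coords(lon=wrap_lon(lon)).sortby("lon")
        lon = ds["lon"].values
    for ax in ("lon", "lat"):
        vals = ds[ax].values
        if vals.size >= 2:
            step = np.diff(vals)
            if step.min() <= 0 or np.ptp(step) > 1e-6:
                raise ValueError(f"irregular {ax} axis")
    if "time" in ds.coords and ds["time"].size >= 2:
        t = pd.to_datetime(ds["time"].values)
        deltas = np.diff(t) / pd.Timedelta(days=1)
        if np.any(deltas > 1.5):
            i = int(np.argmax(deltas > 1.5))
            missing = t[i] + pd.Timedelta(days=1)
            raise ValueError(f"time axis gap: missing {missing.date()}")
    return ds


def write_daily_products(daily: pd.DataFrame, path_csv, path_geojson=None):
    """Write the tidy daily-products table and per-animal trajectory GeoJSON.

    ``daily`` must carry at least animal_id, date, lon, lat; the velocity,
    persistence and environmental columns are written when present.
    Animals with a single day are kept in the table but skipped in the
    GeoJSON (a LineString needs two points).
    """
    df = daily.copy()
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    df.to_csv(path_csv, index=False, float_format="%.10g")
    if path_geojson is not None:
        feats = []
        for aid, sub in daily.groupby("animal_id", sort=True):
            coords = [[round(float(x), 8), round(float(y), 8)]
                      for x, y in zip(sub["lon"], sub["lat"])]
            if len(coords) < 2:
                continue
            feats.append({
                "type": "Feature",
                "properties": {"animal_id": str(aid)},
                "geometry": {"type": "LineString", "coordinates": coords},
            })
        with open(path_geojson, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def read_geojson_tracks(path):
    """Read trajectory GeoJSON back into {animal_id: [(lon, lat), ...]}."""
    with open(path) as fh:
        fc = json.load(fh)
    return {f["properties"]["animal_id"]: [tuple(c) for c in f["geometry"]["coordinates"]]
            for f in fc["features"]}


def write_summary_tsv(table: pd.DataFrame, path):
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
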