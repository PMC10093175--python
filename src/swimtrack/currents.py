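"""Current correction: decompose daily ground motion into current + swimming.

The central identity is the vector subtraction

    swim = ground - current

applied day by day: the ground velocity comes from consecutive daily
regularized positions, the current is sampled from a gridded ocean
product at the segment's start position and date (m/s, converted to
km/day by the exact factor 86.4), and the residual is the animal's
active swimming velocity.  Integrating the swim vectors from the first
regularized position rebuilds the current-corrected trajectory — the
path the animal would have traced through still water.

Missing environmental samples propagate as missing (never zero-filled):
a day without a current estimate has no swim vector and is excluded from
downstream statistics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

from . import geodesy as geo
from .geodesy import MS_TO_KMDAY


def _grid_axis(ds, name):
    return ds[name].values.astype(float)


def sample_field(ds: xr.Dataset, var: str, lon, lat, when):
    """Bilinear sample of one variable at (lon, lat) on the matching time slice.

    Daily variables use the nearest day; weekly variables (time axis
    named ``week``) use the containing week.  Missing (NaN) neighbours
    are excluded with renormalized weights; if all four neighbours are
    missing the result is NaN.  Queries outside the grid extent or time
    span return NaN.
    """
    da = ds[var]
    tdim = "week" if "week" in da.dims else ("time" if "time" in da.dims else None)
    if tdim is not None:
        tvals = pd.to_datetime(ds[tdim].values)
        t = pd.Timestamp(when)
        if tdim == "time":
            i = int(np.argmin(np.abs((tvals - t).total_seconds())))
            if abs((tvals[i] - t).total_seconds()) > 5 * 86400:
                return float("nan")
        else:
            below = np.flatnonzero(tvals <= t)
            if below.size == 0 or t >= tvals[-1] + pd.Timedelta(days=7):
                return float("nan")
            i = int(below[-1])
        plane = da.isel({tdim: i}).values
    else:
        plane = da.values
    ydim, xdim = da.dims[-2], da.dims[-1]
    lons, lats = _grid_axis(ds, xdim), _grid_axis(ds, ydim)
    return _bilinear(plane, lons, lats, float(lon), float(lat))


def _bilinear(plane, lons, lats, lon, lat):
    if not (lons[0] <= lon <= lons[-1] and lats[0] <= lat <= lats[-1]):
        return float("nan")
    i = np.clip(np.searchsorted(lons, lon) - 1, 0, lons.size - 2)
    j = np.clip(np.searchsorted(lats, lat) - 1, 0, lats.size - 2)
    x = (lon - lons[i]) / (lons[i + 1] - lons[i])
    y = (lat - lats[j]) / (lats[j + 1] - lats[j])
    vals = np.array([plane[j, i], plane[j, i + 1], plane[j + 1, i], plane[j + 1, i + 1]])
    w = np.array([(1 - x) * (1 - y), x * (1 - y), (1 - x) * y, x * y])
    ok = np.isfinite(vals)
    if not ok.any() or w[ok].sum() == 0:
        return float("nan")
    return float((vals[ok] * w[ok]).sum() / w[ok].sum())


def decompose(track: pd.DataFrame, field, sample_at="mid") -> pd.DataFrame:
    """Swim/current/ground decomposition of one animal's regularized track.

    ``track`` is a RegularTrack table (animal_id, date, lon, lat);
    ``field`` is an xarray Dataset with u, v in m/s (a SyntheticField's
    ``dataset`` attribute is accepted directly).  Returns one row per
    day pair with ground/current/swim east+north components (km/day),
    swim speed, and the current-corrected position at each day (the
    corrected trajectory starts at the first regularized position).
    Days with a missing current sample have NaN swim components and the
    corrected trajectory holds position across them.

    ``sample_at`` chooses where along each daily segment the current is
    sampled: ``"mid"`` (default) uses the segment midpoint — the
    one-point quadrature of the along-path current, whose error is
    second-order in the field gradient — while ``"start"`` uses the
    segment's first position (first-order error; kept for sensitivity
    analyses).  The sample date is the segment's start day either way.
    """
    ds = getattr(field, "dataset", field)
    if sample_at not in ("mid", "start"):
        raise ValueError("sample_at must be 'mid' or 'start'")
    if len(track) < 2:
        raise ValueError("decompose needs a track of length >= 2")
    t = track.reset_index(drop=True)
    n = len(t)
    dates = pd.to_datetime(t["date"])
    dt = (dates.diff().dt.total_seconds() / 86400.0).to_numpy()
    ge = np.full(n - 1, np.nan)
    gn = np.full(n - 1, np.nan)
    cu = np.full(n - 1, np.nan)
    cv = np.full(n - 1, np.nan)
    for i in range(n - 1):
        ge[i], gn[i] = geo.velocity_between(t["lon"][i], t["lat"][i],
                                            t["lon"][i + 1], t["lat"][i + 1], dt[i + 1])
        if sample_at == "mid":
            plon = (t["lon"][i] + t["lon"][i + 1]) / 2.0
            plat = (t["lat"][i] + t["lat"][i + 1]) / 2.0
        else:
            plon, plat = t["lon"][i], t["lat"][i]
        u = sample_field(ds, "u", plon, plat, dates[i])
        v = sample_field(ds, "v", plon, plat, dates[i])
        cu[i], cv[i] = u * MS_TO_KMDAY, v * MS_TO_KMDAY
    se, sn = ge - cu, gn - cv

    clon = np.empty(n)
    clat = np.empty(n)
    clon[0], clat[0] = t["lon"][0], t["lat"][0]
    for i in range(n - 1):
        if np.isfinite(se[i]) and np.isfinite(sn[i]):
            clon[i + 1], clat[i + 1] = geo.displace(clon[i], clat[i], se[i], sn[i], dt[i + 1])
        else:
            clon[i + 1], clat[i + 1] = clon[i], clat[i]

    out = pd.DataFrame({
        "animal_id": t["animal_id"],
        "date": dates,
        "lon": t["lon"], "lat": t["lat"],
        "corr_lon": clon, "corr_lat": clat,
        "ground_east": np.append(ge, np.nan), "ground_north": np.append(gn, np.nan),
        "cur_east": np.append(cu, np.nan), "cur_north": np.append(cv, np.nan),
        "swim_east": np.append(se, np.nan), "swim_north": np.append(sn, np.nan),
    })
    out["swim_speed"] = geo.speed_kmday(out["swim_east"], out["swim_north"])
    out["cur_speed"] = geo.speed_kmday(out["cur_east"], out["cur_north"])
    return out


def annotate(track: pd.DataFrame, field, sargassum_radius_km=1.0) -> pd.DataFrame:
    """Per-day environmental covariates at the regularized daily positions.

    SST by bilinear interpolation of the day's slice; sargassum as the
    mean of all grid cells whose centers lie within ``sargassum_radius_km``
    of the position (an empty set yields missing, not zero).
    """
    ds = getattr(field, "dataset", field)
    rows = []
    if "sargassum" in ds:
        da = ds["sargassum"]
        slons, slats = _grid_axis(ds, da.dims[-1]), _grid_axis(ds, da.dims[-2])
    for _, r in track.iterrows():
        sst = sample_field(ds, "sst", r["lon"], r["lat"], r["date"]) if "sst" in ds else np.nan
        sarg = np.nan
        if "sargassum" in ds:
            sarg = _disk_mean(ds, "sargassum", slons, slats, r["lon"], r["lat"],
                              r["date"], sargassum_radius_km)
        rows.append({"animal_id": r["animal_id"], "date": r["date"],
                     "sst": sst, "sargassum": sarg})
    return pd.DataFrame(rows)


def _disk_mean(ds, var, lons, lats, lon, lat, when, radius_km):
    da = ds[var]
    tdim = "week" if "week" in da.dims else "time"
    tvals = pd.to_datetime(ds[tdim].values)
    t = pd.Timestamp(when)
    if tdim == "week":
        below = np.flatnonzero(tvals <= t)
        if below.size == 0 or t >= tvals[-1] + pd.Timedelta(days=7):
            return float("nan")
        i = int(below[-1])
    else:
        i = int(np.argmin(np.abs((tvals - t).total_seconds())))
    plane = da.isel({tdim: i}).values
    # great-circle distance from the position to every cell center within a
    # generous lon/lat window (the radius is ~1 km; window keeps this cheap)
    dd = radius_km / 111.0 * 3
    ii = np.flatnonzero(np.abs(lons - lon) <= max(dd / max(np.cos(np.radians(lat)), .1), 1e-9))
    jj = np.flatnonzero(np.abs(lats - lat) <= dd)
    if ii.size == 0 or jj.size == 0:
        return float("nan")
    LON, LAT = np.meshgrid(lons[ii], lats[jj])
    d = geo.great_circle_km(LON.ravel(), LAT.ravel(), lon, lat)
    sel = d <= radius_km
    if not sel.any():
        return float("nan")
    vals = plane[np.ix_(jj, ii)].ravel()[sel]
    vals = vals[np.isfinite(vals)]
    return float(vals.mean()) if vals.size else float("nan")


def alignment_series(decomp: pd.DataFrame) -> pd.DataFrame:
    """Signed swim-vs-current angle per day, classified opposing/following.

    The angle is heading(swim) - heading(current) wrapped to (-180, 180].
    |angle| >= 90 degrees is "opposing" (the boundary counts as
    opposing), otherwise "following".  Days with a missing or zero
    vector are skipped.
    """
    d = decomp
    ok = (np.isfinite(d["swim_east"]) & np.isfinite(d["cur_east"])
          & (geo.speed_kmday(d["swim_east"], d["swim_north"]) > 0)
          & (geo.speed_kmday(d["cur_east"], d["cur_north"]) > 0))
    sub = d.loc[ok]
    hs = geo.vector_heading_deg(sub["swim_east"].to_numpy(), sub["swim_north"].to_numpy())
    hc = geo.vector_heading_deg(sub["cur_east"].to_numpy(), sub["cur_north"].to_numpy())
    ang = (hs - hc + 180.0) % 360.0 - 180.0
    ang = np.where(ang == -180.0, 180.0, ang)
    return pd.DataFrame({"animal_id": sub["animal_id"].to_numpy(),
                         "date": sub["date"].to_numpy(),
                         "angle_deg": ang,
                         "relation": np.where(np.abs(ang) >= 90.0, "opposing", "following")})
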