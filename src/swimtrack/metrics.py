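"""Per-day movement statistics, dispersal classification, track summaries.

The central quantity is the daily persistence velocity

    V_t = L_t * cos(theta_t)

with L_t the straight-line displacement (km/day) between successive
current-corrected daily positions and theta_t the signed turning angle
(radians) between the swimming-velocity vectors of days t-1 and t.  V_t
is the signed tendency of the day's displacement to continue in the
previous day's swimming direction: V = L for straight-ahead motion,
V = -L for a full reversal, V = 0 for a right-angle turn, and
|V| <= L always.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from . import geodesy as geo
from .circular import circ_mean_sd
from .ssm import polygon_distance_km


def persistence_series(decomp: pd.DataFrame) -> pd.DataFrame:
    """Daily step length, turning angle and persistence velocity.

    ``decomp`` is one animal's decomposition table (current-corrected
    positions + swim vectors).  Steps are measured along the corrected
    trajectory; the turning angle on day t is the signed angle from the
    swim vector of day t-1 to that of day t.  The first day has no
    turning angle and is excluded; days adjacent to a missing or
    zero-length swim vector get missing V.
    """
    d = decomp.reset_index(drop=True)
    if len(d) < 3:
        raise ValueError("persistence needs >= 3 daily positions (two steps)")
    lon = d["corr_lon"].to_numpy()
    lat = d["corr_lat"].to_numpy()
    L = geo.great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])  # step of day t -> t+1
    se = d["swim_east"].to_numpy()
    sn = d["swim_north"].to_numpy()
    # signed angle between successive swim vectors, in (-pi, pi]
    ang = np.arctan2(se, sn)
    theta = np.diff(ang)
    theta = (theta + np.pi) % (2 * np.pi) - np.pi
    theta = np.where(theta == -np.pi, np.pi, theta)
    mag = np.hypot(se, sn)
    bad = ~np.isfinite(mag[:-1]) | ~np.isfinite(mag[1:]) | (mag[:-1] == 0) | (mag[1:] == 0)
    theta = np.where(bad[: len(theta)], np.nan, theta)
    # rows are days t = 2..n (steps 2..n); step t uses turning angle between
    # swim vectors of steps t-1 and t
    step = L[1:]
    turn = theta[: len(step)]
    V = step * np.cos(turn)
    out = pd.DataFrame({
        "animal_id": d["animal_id"].to_numpy()[1: 1 + len(step)],
        "date": d["date"].to_numpy()[1: 1 + len(step)],
        "lon": d["lon"].to_numpy()[1: 1 + len(step)],
        "lat": d["lat"].to_numpy()[1: 1 + len(step)],
        "step_km": step,
        "turn_rad": turn,
        "persistence": V,
    })
    return out


def classify_dispersal(fixes: pd.DataFrame, island: Polygon, radius_km=10.0) -> pd.DataFrame:
    """Label each animal dispersive/residential by the 10-km buffer rule.

    Applied to the raw (pre-filter) fixes: an animal is dispersive iff
    any fix lies more than ``radius_km`` beyond the island polygon; the
    exit day is the date of the first exceedance.  Animals without any
    viable fix are labelled undetermined.  The result is invariant to
    the input row order.
    """
    rows = []
    for aid, sub in fixes.groupby("animal_id", sort=True):
        sub = sub.sort_values("time", kind="stable")
        ok = np.isfinite(sub["lon"].to_numpy()) & np.isfinite(sub["lat"].to_numpy())
        if not ok.any():
            rows.append({"animal_id": aid, "label": "undetermined", "exit_day": pd.NaT})
            continue
        d = polygon_distance_km(sub["lon"].to_numpy()[ok], sub["lat"].to_numpy()[ok], island)
        beyond = d > radius_km
        if beyond.any():
            first = np.flatnonzero(beyond)[0]
            exit_day = pd.to_datetime(sub["time"].to_numpy()[ok][first])
            rows.append({"animal_id": aid, "label": "dispersive", "exit_day": exit_day})
        else:
            rows.append({"animal_id": aid, "label": "residential", "exit_day": pd.NaT})
    return pd.DataFrame(rows, columns=["animal_id", "label", "exit_day"])


def initial_heading(fixes: pd.DataFrame, declination_deg=0.0) -> float:
    """Release heading from the first two distinct fixes, degrees from
    (magnetic) north.

    Coincident leading fixes are skipped until the first distinct
    position.  With the default declination of 0 the heading is from
    true north.
    """
    sub = fixes.sort_values("time", kind="stable").reset_index(drop=True)
    if len(sub) < 2:
        raise ValueError("need at least two fixes")
    lon0, lat0 = sub["lon"].iloc[0], sub["lat"].iloc[0]
    for i in range(1, len(sub)):
        if (sub["lon"].iloc[i], sub["lat"].iloc[i]) != (lon0, lat0):
            true = geo.bearing_deg(lon0, lat0, sub["lon"].iloc[i], sub["lat"].iloc[i])
            return float(geo.to_magnetic(true, declination_deg))
    raise ValueError("all fixes coincident; heading undefined")


def track_summary(track: pd.DataFrame, decomp: pd.DataFrame | None = None,
                  annotation: pd.DataFrame | None = None) -> dict:
    """Per-animal summary statistics of one regularized daily track.

    Returns duration (days), mean and SD of the 24-h displacement (km),
    circular-mean bearing of the daily movement directions (degrees from
    true north), mean/SD SST (degC), mean/SD current speed (km/day),
    mean/SD swimming speed (km/day), and the total displacement (km,
    release to last position).  Velocity statistics are missing for a
    single-day track.
    """
    t = track.reset_index(drop=True)
    out = {"animal_id": t["animal_id"].iloc[0], "duration_days": len(t)}
    if len(t) < 2:
        out.update({"mean_step_km": np.nan, "sd_step_km": np.nan,
                    "mean_bearing_deg": np.nan, "total_displacement_km": 0.0})
    else:
        lon, lat = t["lon"].to_numpy(), t["lat"].to_numpy()
        steps = geo.great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        brg = geo.bearing_deg(lon[:-1], lat[:-1], lon[1:], lat[1:])
        brg = brg[np.isfinite(brg)]
        mean_b = circ_mean_sd(brg)[0] if brg.size else np.nan
        out.update({
            "mean_step_km": float(steps.mean()),
            "sd_step_km": float(steps.std(ddof=1)) if steps.size > 1 else np.nan,
            "mean_bearing_deg": mean_b,
            "total_displacement_km": float(geo.great_circle_km(lon[0], lat[0], lon[-1], lat[-1])),
        })
    if annotation is not None and len(annotation):
        sst = annotation["sst"].dropna()
        out["mean_sst"] = float(sst.mean()) if len(sst) else np.nan
        out["sd_sst"] = float(sst.std(ddof=1)) if len(sst) > 1 else np.nan
    if decomp is not None and len(decomp):
        cs = decomp["cur_speed"].dropna()
        ss = decomp["swim_speed"].dropna()
        out["mean_cur_speed"] = float(cs.mean()) if len(cs) else np.nan
        out["sd_cur_speed"] = float(cs.std(ddof=1)) if len(cs) > 1 else np.nan
        out["mean_swim_speed"] = float(ss.mean()) if len(ss) else np.nan
        out["sd_swim_speed"] = float(ss.std(ddof=1)) if len(ss) > 1 else np.nan
    return out


SUMMARY_COLUMNS = ["animal_id", "period", "age_class", "duration_days",
                   "mean_step_km", "sd_step_km", "mean_bearing_deg",
                   "mean_sst", "sd_sst", "mean_cur_speed", "sd_cur_speed",
                   "mean_swim_speed", "sd_swim_speed", "total_displacement_km"]


def cohort_summary(tracks, decomps, annotations, covariates=None) -> pd.DataFrame:
    """Summary table with one row per animal (release-study table layout)."""
    rows = []
    for aid, track in tracks.groupby("animal_id", sort=True):
        row = track_summary(track.reset_index(drop=True),
                            decomps.get(aid), annotations.get(aid))
        if covariates is not None:
            meta = covariates.loc[covariates["animal_id"] == aid]
            if len(meta):
                row["period"] = meta["period"].iloc[0]
                row["age_class"] = meta["age_class"].iloc[0]
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    return df[cols + [c for c in df.columns if c not in cols]]
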