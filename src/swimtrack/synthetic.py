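"""Synthetic study world: current fields, swimming turtles, drifters, ARGOS noise.

This module generates data with the statistical structure the analysis
chain assumes, so that every downstream stage (regularization, current
correction, movement metrics, circular tests, persistence model) can be
verified against known ground truth without any external data product.

The motion model is the minimal one consistent with goal-directed
swimming in an advecting ocean: at each fine time step an animal draws a
heading from a von Mises law centred on the bearing to its goal (with
concentration kappa), a speed from a Gamma law with a stated mean and
coefficient of variation, and its ground displacement is the sum of that
swim vector and the ocean-current vector sampled at its position.  By
construction ground = swim + current holds exactly at every step; the
simulator records the exact swim vectors so the current-correction stage
can be tested for recovery.

Two cohort scenarios mirror a winter and a summer release off a small
Caribbean island: "jan" produces heterogeneous goal bearings (radial
dispersal) plus a residential fraction of tight loiterers that never
leave the island's 10 km buffer; "jul" produces a common northward drive
into a clockwise (Rankine) vortex.  Current magnitudes, swim speeds
(18-60 km/day scale), fix rates (over-dispersed, roughly 1-17 per day)
and elliptical ARGOS errors are set to the scale of juvenile green
turtle telemetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import Polygon

from . import geodesy as geo
from .geodesy import MS_TO_KMDAY

# a small synthetic island (roughly the footprint of Grand Cayman)
ISLAND_CENTER = (-81.25, 19.32)


def island_polygon():
    """A synthetic island coastline polygon (lon/lat degrees), ~35 x 10 km."""
    lon0, lat0 = ISLAND_CENTER
    t = np.linspace(0, 2 * np.pi, 33)
    a_km, b_km = 17.0, 5.0
    fwd, inv = geo.local_plane(lon0, lat0)
    lon, lat = inv(a_km * np.cos(t), b_km * np.sin(t))
    return Polygon(zip(lon, lat))


@dataclass
class CurrentFieldSpec:
    """Specification of a gridded synthetic ocean field."""

    kind: str = "uniform"            # uniform | vortex | composite
    u0: float = 0.0                  # background eastward current, m/s
    v0: float = 0.0                  # background northward current, m/s
    vortex_center: tuple = (-80.2, 20.6)   # lon, lat
    vortex_peak_ms: float = 0.5      # peak tangential speed, m/s
    vortex_radius_km: float = 120.0  # Rankine core radius
    vortex_taper_km: float | None = None   # e-folding of the outer decay; default 2x radius
    lon_range: tuple = (-85.0, -77.0)
    lat_range: tuple = (16.0, 23.0)
    resolution_deg: float = 1.0 / 12.0
    sargassum_resolution_deg: float = 0.01   # the algae product's finer grid
    days: int = 40
    start: str = "2022-01-22"

    def __post_init__(self):
        if self.vortex_peak_ms < 0 or self.resolution_deg <= 0:
            raise ValueError("invalid field spec")
        if self.lon_range[1] <= self.lon_range[0] or self.lat_range[1] <= self.lat_range[0]:
            raise ValueError("empty grid extent")


class SyntheticField:
    """A gridded field plus the closed-form current evaluator it was built from.

    ``dataset`` is a CF-style xarray Dataset with daily u, v (m/s), daily
    sst (degC) and weekly sargassum (g/m2).  ``current_at(lon, lat)``
    evaluates the analytic current (u, v in m/s) exactly, independent of
    the grid, and is the oracle downstream interpolation is tested
    against.
    """

    def __init__(self, dataset, spec):
        self.dataset = dataset
        self.spec = spec

    def current_at(self, lon, lat):
        return _analytic_current(self.spec, lon, lat)

    def current_kmday(self, lon, lat):
        u, v = self.current_at(lon, lat)
        return u * MS_TO_KMDAY, v * MS_TO_KMDAY


def _analytic_current(spec, lon, lat):
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    u = np.full(np.broadcast(lon, lat).shape, float(spec.u0))
    v = np.full(np.broadcast(lon, lat).shape, float(spec.v0))
    if spec.kind == "uniform":
        pass
    elif spec.kind in ("vortex", "composite"):
        if spec.kind == "vortex":
            u = np.zeros_like(u)
            v = np.zeros_like(v)
        fwd, _ = geo.local_plane(*spec.vortex_center)
        x, y = fwd(lon, lat)
        r = np.hypot(x, y)
        rc = spec.vortex_radius_km
        taper = spec.vortex_taper_km if spec.vortex_taper_km is not None else 2.0 * rc
        with np.errstate(divide="ignore", invalid="ignore"):
            # solid-body core, 1/r decay outside, with an exponential outer
            # taper so the eddy is compact (real mesoscale eddies are)
            vt = np.where(r <= rc, spec.vortex_peak_ms * r / rc,
                          spec.vortex_peak_ms * rc / np.maximum(r, 1e-12)
                          * np.exp(-(np.maximum(r - rc, 0.0)) / taper))
            # clockwise circulation: tangential unit vector (y, -x)/r
            uu = np.where(r > 1e-12, vt * y / np.maximum(r, 1e-12), 0.0)
            vv = np.where(r > 1e-12, -vt * x / np.maximum(r, 1e-12), 0.0)
        u = u + uu
        v = v + vv
    else:
        raise ValueError(f"unknown field kind {spec.kind!r}")
    if np.ndim(lon) == 0 and np.ndim(lat) == 0:
        return float(u), float(v)
    return u, v


def build_field(spec: CurrentFieldSpec, seed=0) -> SyntheticField:
    """Build the gridded dataset (u, v, sst, sargassum) for a field spec.

    u and v are evaluated from the closed-form current; sst is a smooth
    latitudinal gradient with small smooth day-to-day variation, kept
    inside [20, 33] degC; sargassum is a sparse, patchy, non-negative
    weekly field.
    """
    rng = np.random.default_rng(seed)
    lon = np.arange(spec.lon_range[0], spec.lon_range[1] + spec.resolution_deg / 2,
                    spec.resolution_deg)
    lat = np.arange(spec.lat_range[0], spec.lat_range[1] + spec.resolution_deg / 2,
                    spec.resolution_deg)
    if lon.size < 2 or lat.size < 2:
        raise ValueError("empty grid")
    time = pd.date_range(spec.start, periods=spec.days, freq="D")
    LON, LAT = np.meshgrid(lon, lat)
    u2, v2 = _analytic_current(spec, LON, LAT)
    u = np.broadcast_to(u2, (spec.days,) + u2.shape).copy()
    v = np.broadcast_to(v2, (spec.days,) + v2.shape).copy()

    # SST: latitudinal gradient + gentle seasonal-ish daily drift
    base = 29.5 - 0.35 * (LAT - spec.lat_range[0])
    drift = 0.3 * np.sin(2 * np.pi * np.arange(spec.days) / 30.0)
    sst = np.clip(base[None, :, :] + drift[:, None, None]
                  + rng.normal(0, 0.05, (spec.days,) + LON.shape), 20.0, 33.0)

    # Sargassum: weekly sparse Gaussian patches on its own (finer) grid,
    # non-negative, as the algae-density product is distributed
    lon_s = np.arange(spec.lon_range[0], spec.lon_range[1] + spec.sargassum_resolution_deg / 2,
                      spec.sargassum_resolution_deg).astype(np.float64)
    lat_s = np.arange(spec.lat_range[0], spec.lat_range[1] + spec.sargassum_resolution_deg / 2,
                      spec.sargassum_resolution_deg).astype(np.float64)
    weeks = pd.date_range(spec.start, periods=max(1, (spec.days + 6) // 7), freq="7D")
    sarg = np.zeros((len(weeks), lat_s.size, lon_s.size), dtype=np.float32)
    n_patch = 25
    for w in range(len(weeks)):
        for _ in range(n_patch):
            clon = rng.uniform(*spec.lon_range)
            clat = rng.uniform(*spec.lat_range)
            amp = rng.gamma(2.0, 2.0)           # g/m2
            sig = rng.uniform(0.2, 0.6)         # degrees
            # add within a local window (the patch support) to keep it cheap
            i0, i1 = np.searchsorted(lon_s, [clon - 4 * sig, clon + 4 * sig])
            j0, j1 = np.searchsorted(lat_s, [clat - 4 * sig, clat + 4 * sig])
            if i1 <= i0 or j1 <= j0:
                continue
            gx = np.exp(-((lon_s[i0:i1] - clon) ** 2) / (2 * sig**2))
            gy = np.exp(-((lat_s[j0:j1] - clat) ** 2) / (2 * sig**2))
            sarg[w, j0:j1, i0:i1] += amp * np.outer(gy, gx).astype(np.float32)
    sarg[sarg < 0.05] = 0.0

    ds = xr.Dataset(
        {
            "u": (("time", "lat", "lon"), u, {"units": "m s-1"}),
            "v": (("time", "lat", "lon"), v, {"units": "m s-1"}),
            "sst": (("time", "lat", "lon"), sst, {"units": "degC"}),
            "sargassum": (("week", "lat_hi", "lon_hi"), sarg, {"units": "g m-2"}),
        },
        coords={"time": time, "week": weeks, "lon": lon, "lat": lat,
                "lon_hi": lon_s, "lat_hi": lat_s},
        attrs={"Conventions": "CF-1.8", "title": "synthetic ocean surface field"},
    )
    return SyntheticField(ds, spec)


@dataclass
class SwimmerSpec:
    """Behavioural parameters of one simulated animal."""

    animal_id: str = "sim-001"
    release: tuple = (-81.25, 19.45)   # lon, lat
    goal: tuple | None = (-84.0, 16.5)
    mean_swim_kmday: float = 35.0
    speed_cv: float = 0.3
    kappa: float = 8.0                 # von Mises heading concentration
    duration_days: float = 15.0
    dt_days: float = 0.05
    start: str = "2022-01-22"
    period: str = "jan"
    age_class: str = "1-2"
    weight_kg: float = 6.0

    def __post_init__(self):
        if self.kappa < 0 or self.mean_swim_kmday < 0 or self.dt_days <= 0:
            raise ValueError("invalid swimmer spec")


def _gamma_speeds(rng, n, mean, cv):
    if mean == 0:
        return np.zeros(n)
    if cv <= 0:
        return np.full(n, mean)
    shape = 1.0 / cv**2
    return rng.gamma(shape, mean / shape, n)


def simulate_swimmer(spec: SwimmerSpec, field: SyntheticField, seed=0):
    """Integrate one goal-directed track through a current field.

    Returns a DataFrame with one row per fine step: time, lon, lat (the
    position at the *start* of the step), the swim and current velocity
    components (km/day) applied over the step.  The final position is
    appended as a last row with NaN velocities.  Tracks that exit the
    field extent are truncated with a warning flag in ``attrs``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration_days / spec.dt_days))
    t0 = pd.Timestamp(spec.start)
    lon, lat = spec.release
    lons, lats, se, sn, ce, cn = [], [], [], [], [], []
    lo, hi = field.spec.lon_range, field.spec.lat_range
    truncated = False
    for i in range(n):
        if not (lo[0] <= lon <= lo[1] and hi[0] <= lat <= hi[1]):
            truncated = True
            break
        if spec.goal is not None and spec.kappa > 0:
            try:
                mu = np.radians(geo.bearing_deg(lon, lat, spec.goal[0], spec.goal[1]))
            except ValueError:       # sitting exactly on the goal
                mu = rng.uniform(0, 2 * np.pi)
            head = rng.vonmises(mu, spec.kappa)
        else:
            head = rng.uniform(-np.pi, np.pi)
        speed = _gamma_speeds(rng, 1, spec.mean_swim_kmday, spec.speed_cv)[0]
        sw_e, sw_n = speed * np.sin(head), speed * np.cos(head)
        cu, cv_ = field.current_kmday(lon, lat)
        lons.append(lon)
        lats.append(lat)
        se.append(sw_e)
        sn.append(sw_n)
        ce.append(cu)
        cn.append(cv_)
        lon, lat = geo.displace(lon, lat, sw_e + cu, sw_n + cv_, spec.dt_days)
    lons.append(lon)
    lats.append(lat)
    k = len(lons)
    df = pd.DataFrame({
        "animal_id": spec.animal_id,
        "time": t0 + pd.to_timedelta(np.arange(k) * spec.dt_days, unit="D"),
        "lon": lons,
        "lat": lats,
        "swim_east": se + [np.nan],
        "swim_north": sn + [np.nan],
        "cur_east": ce + [np.nan],
        "cur_north": cn + [np.nan],
    })
    df.attrs["truncated"] = truncated
    return df


def simulate_drifter(release, field: SyntheticField, duration_days=10.0, seed=0,
                     dt_days=10.0 / (24 * 60 * 6)):
    """A passive drifter: a swimmer with zero swim speed, 10-minute steps."""
    spec = SwimmerSpec(animal_id="drifter", release=tuple(release), goal=None,
                       mean_swim_kmday=0.0, kappa=0.0,
                       duration_days=duration_days, dt_days=dt_days,
                       start=field.spec.start)
    return simulate_swimmer(spec, field, seed=seed)


def true_daily_track(fine_track, dt_days):
    """Daily positions and daily-mean swim/current vectors from a fine track.

    Day d's mean swim vector averages the per-step vectors applied during
    [d, d+1); the daily position is the position at the start of each day.
    """
    df = fine_track
    t0 = df["time"].iloc[0]
    day = ((df["time"] - t0) / pd.Timedelta(days=1) + 1e-9).astype(int)
    steps_per_day = int(round(1.0 / dt_days))
    rows = []
    for d in sorted(day.unique()):
        sub = df[day == d]
        first = sub.iloc[0]
        complete = sub["swim_east"].notna().sum() >= steps_per_day
        rows.append({
            "day": d, "time": first["time"], "lon": first["lon"], "lat": first["lat"],
            "swim_east": sub["swim_east"].mean(), "swim_north": sub["swim_north"].mean(),
            "cur_east": sub["cur_east"].mean(), "cur_north": sub["cur_north"].mean(),
            "complete": complete,
        })
    return pd.DataFrame(rows)


@dataclass
class ArgosNoiseSpec:
    """Timing and error model of satellite fixes."""

    fixes_per_day_mean: float = 12.6
    fixes_per_day_dispersion: float = 4.0     # negative binomial size parameter
    class_frequencies: dict = dc_field(default_factory=lambda: {
        "3": 0.15, "2": 0.25, "1": 0.25, "0": 0.15, "A": 0.12, "B": 0.08})
    class_smaj_km: dict = dc_field(default_factory=lambda: {
        "3": 0.25, "2": 0.5, "1": 1.0, "0": 2.0, "A": 3.0, "B": 5.0})

    def __post_init__(self):
        if any(v <= 0 for v in self.class_smaj_km.values()):
            raise ValueError("ellipse scales must be positive")


def observe_argos(track, spec: ArgosNoiseSpec, seed=0):
    """Thin a true track into noisy ARGOS-like fixes.

    Per whole day the number of fixes is negative binomial with the
    stated mean and dispersion; fix times are uniform within the day and
    strictly increasing.  Each fix gets a quality class, an error
    ellipse (semi-major from the class scale with lognormal spread,
    semi-minor a uniform fraction of it, uniform orientation), and a
    position equal to the true track position at that time plus a draw
    from the ellipse's bivariate normal.  Deterministic under a fixed
    seed.
    """
    rng = np.random.default_rng(seed)
    t = track["time"]
    t0 = t.iloc[0]
    total_days = (t.iloc[-1] - t0) / pd.Timedelta(days=1)
    n_days = max(1, int(np.floor(total_days + 1e-9)))
    mu, size = spec.fixes_per_day_mean, spec.fixes_per_day_dispersion
    p = size / (size + mu)
    counts = rng.negative_binomial(size, p, n_days)
    classes = list(spec.class_frequencies)
    freqs = np.array([spec.class_frequencies[c] for c in classes], dtype=float)
    freqs = freqs / freqs.sum()

    tt = (t - t0) / pd.Timedelta(days=1)
    rows = []
    for d in range(n_days):
        times = np.sort(rng.uniform(d, min(d + 1, total_days), counts[d]))
        for ft in times:
            lon = np.interp(ft, tt, track["lon"])
            lat = np.interp(ft, tt, track["lat"])
            qc = classes[rng.choice(len(classes), p=freqs)]
            smaj = spec.class_smaj_km[qc] * rng.lognormal(0.0, 0.3)
            smin = smaj * rng.uniform(0.4, 1.0)
            ori = rng.uniform(0.0, 360.0)
            e, nn = _ellipse_noise(rng, smaj, smin, ori)
            nlon, nlat = geo.displace(lon, lat, e, nn, 1.0)
            rows.append({"animal_id": track["animal_id"].iloc[0]
                         if "animal_id" in track else "sim",
                         "time": t0 + pd.Timedelta(days=ft),
                         "lon": nlon, "lat": nlat,
                         "smaj_km": smaj, "smin_km": smin, "eor_deg": ori,
                         "qclass": qc})
    cols = ["animal_id", "time", "lon", "lat", "smaj_km", "smin_km", "eor_deg", "qclass"]
    return pd.DataFrame(rows, columns=cols)


def ellipse_cov(smaj_km, smin_km, eor_deg):
    """2x2 east/north covariance of an error ellipse.

    Orientation is the bearing of the semi-major axis, degrees clockwise
    from north; axes are 1-sigma lengths in km.
    """
    psi = np.radians(eor_deg)
    ux, uy = np.sin(psi), np.cos(psi)          # major-axis unit vector (E, N)
    vx, vy = np.cos(psi), -np.sin(psi)
    a2, b2 = smaj_km**2, smin_km**2
    return np.array([[a2 * ux * ux + b2 * vx * vx, a2 * ux * uy + b2 * vx * vy],
                     [a2 * ux * uy + b2 * vx * vy, a2 * uy * uy + b2 * vy * vy]])


def _ellipse_noise(rng, smaj, smin, eor_deg):
    z = rng.standard_normal(2)
    psi = np.radians(eor_deg)
    e = smaj * z[0] * np.sin(psi) + smin * z[1] * np.cos(psi)
    n = smaj * z[0] * np.cos(psi) - smin * z[1] * np.sin(psi)
    return e, n


def make_persistence_dataset(n_animals=20, n_days=15, period_effect=6.2,
                             intercept=-0.7, ar1=0.5, innovation_sd=6.0,
                             animal_sd=1.5, surface=None, seed=0):
    """Synthetic daily persistence-velocity table with known structure.

    Half the animals are assigned to each tracking period; the response is

        V_it = intercept + period_effect * 1(period == jan) + f(lat, lon)
               + b_i + e_it,   b_i ~ N(0, animal_sd^2),
               e_it AR(1) with coefficient ``ar1`` and the given
               innovation SD.

    ``surface`` is an optional callable f(lat, lon) (defaults to zero —
    a null spatial field).  Null covariates (current speed, SST,
    sargassum, body weight) are generated independent of the response.
    Locations are slow per-animal random walks across the study domain
    so the spatial smoother has support.  Ground truth for every
    component is returned alongside the table.
    """
    rng = np.random.default_rng(seed)
    rows = []
    t0 = pd.Timestamp("2022-01-22")
    for i in range(n_animals):
        period = "jan" if i < n_animals / 2 else "jul"
        b = rng.normal(0, animal_sd)
        lat = rng.uniform(17.0, 22.0)
        lon = rng.uniform(-84.5, -78.0)
        weight = rng.uniform(4.0, 25.0)
        e = 0.0
        for tday in range(n_days):
            e = ar1 * e + rng.normal(0, innovation_sd)
            f = surface(lat, lon) if surface is not None else 0.0
            v = intercept + (period_effect if period == "jan" else 0.0) + f + b + e
            rows.append({"animal_id": f"sim-{i:03d}", "date": t0 + pd.Timedelta(days=tday),
                         "lat": lat, "lon": lon, "persistence": v,
                         "cur_speed": rng.gamma(4.0, 5.0),
                         "sst": 27.0 + rng.normal(0, 0.5),
                         "sargassum": max(0.0, rng.normal(1.0, 1.0)),
                         "weight_kg": weight, "period": period})
            lat += rng.normal(0, 0.12)
            lon += rng.normal(0, 0.12)
    truth = {"intercept": intercept, "period_effect": period_effect, "ar1": ar1,
             "innovation_sd": innovation_sd, "animal_sd": animal_sd}
    return pd.DataFrame(rows), truth


def make_cohort(scenario="jan", n_turtles=30, seed=0, n_residential=None,
                duration_days=15.0, dt_days=0.05):
    """Simulate a full release cohort: field, tracks, fixes, covariates, truth.

    scenario "jan": heterogeneous goal bearings spanning the compass
    (radial dispersal) with ``n_residential`` tight loiterers (default
    16 when n_turtles == 30, scaled proportionally otherwise) that stay
    inside the island's 10 km buffer; moderate background current plus a
    distant clockwise vortex.  scenario "jul": all dispersive, common
    northward goals into the vortex, weaker currents.

    Returns a dict with keys: field, fixes (DataFrame), truth (fine
    tracks, DataFrame), daily_truth, covariates (DataFrame), island
    (shapely Polygon), spec metadata.
    """
    if n_turtles < 1:
        raise ValueError("need at least one animal")
    rng = np.random.default_rng(seed)
    island = island_polygon()
    lon0, lat0 = ISLAND_CENTER
    if scenario == "jan":
        fspec = CurrentFieldSpec(kind="composite", u0=-0.05, v0=0.02,
                                 vortex_center=(-78.8, 22.3), vortex_peak_ms=0.8,
                                 vortex_radius_km=130.0, start="2022-01-22",
                                 days=int(duration_days) + 5)
        if n_residential is None:
            n_residential = int(round(16 * n_turtles / 30))
        release = geo.displace(lon0, lat0 + 0.05, 0.0, 10.0)   # ~10 km north
        period = "jan"
    elif scenario == "jul":
        fspec = CurrentFieldSpec(kind="composite", u0=-0.05, v0=0.10,
                                 vortex_center=(-80.9, 21.3), vortex_peak_ms=0.45,
                                 vortex_radius_km=150.0, start="2022-07-20",
                                 days=int(duration_days) + 5)
        n_residential = 0 if n_residential is None else n_residential
        release = geo.displace(lon0, lat0 - 0.05, 0.0, -10.0)  # ~10 km south
        period = "jul"
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    n_residential = min(n_residential, n_turtles)

    age_classes = ["1-2", "2-3", "3-4"]
    weight_scale = {"1-2": 6.0, "2-3": 14.0, "3-4": 22.0}
    truth_parts, fix_parts, daily_parts, cov_rows = [], [], [], []
    field = build_field(fspec, seed=int(rng.integers(2**31 - 1)))
    for i in range(n_turtles):
        aid = f"{period}-{i + 1:03d}"
        residential = i < n_residential
        age = age_classes[i % 3] if scenario == "jan" else "1-2"
        weight = float(np.round(weight_scale[age] * rng.lognormal(0, 0.12), 1))
        if residential:
            # tight loiterer anchored just off the coastline
            anchor = (lon0 + rng.uniform(-0.1, 0.1), lat0 + rng.uniform(0.05, 0.08))
            spec = SwimmerSpec(animal_id=aid, release=anchor, goal=anchor,
                               mean_swim_kmday=15.0, speed_cv=0.4, kappa=12.0,
                               duration_days=duration_days, dt_days=dt_days,
                               start=fspec.start, period=period, age_class=age,
                               weight_kg=weight)
            # nearshore animals report fewer fixes but of good quality
            # (surface intervals close to land-based receive conditions)
            noise = ArgosNoiseSpec(fixes_per_day_mean=4.2,
                                   fixes_per_day_dispersion=3.0,
                                   class_frequencies={"3": 0.4, "2": 0.4, "1": 0.2})
        else:
            if scenario == "jan":
                brg = (i * 360.0 / max(1, n_turtles - n_residential) +
                       rng.uniform(-15, 15)) % 360.0
            else:
                brg = (0.0 + rng.uniform(-35, 35)) % 360.0
            dist = rng.uniform(350, 650)
            goal = geo.displace(release[0], release[1],
                                dist * np.sin(np.radians(brg)),
                                dist * np.cos(np.radians(brg)))
            spec = SwimmerSpec(animal_id=aid, release=release, goal=goal,
                               mean_swim_kmday=rng.uniform(22, 50), speed_cv=0.3,
                               kappa=rng.uniform(5, 12),
                               duration_days=duration_days, dt_days=dt_days,
                               start=fspec.start, period=period, age_class=age,
                               weight_kg=weight)
            noise = ArgosNoiseSpec()
        sub = int(rng.integers(2**31 - 1))
        fine = simulate_swimmer(spec, field, seed=sub)
        fixes = observe_argos(fine, noise, seed=sub + 1)
        truth_parts.append(fine)
        fix_parts.append(fixes)
        daily = true_daily_track(fine, dt_days)
        daily.insert(0, "animal_id", aid)
        daily_parts.append(daily)
        cov_rows.append({"animal_id": aid, "period": period, "age_class": age,
                         "weight_kg": weight,
                         "residential_truth": residential,
                         "goal_bearing_deg": np.nan if residential else brg,
                         "release_lon": spec.release[0],
                         "release_lat": spec.release[1]})
    return {
        "field": field,
        "fixes": pd.concat(fix_parts, ignore_index=True),
        "truth": pd.concat(truth_parts, ignore_index=True),
        "daily_truth": pd.concat(daily_parts, ignore_index=True),
        "covariates": pd.DataFrame(cov_rows),
        "island": island,
        "scenario": scenario,
        "seed": seed,
    }
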