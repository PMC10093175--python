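"""State-space regularization: buffer filter, random-walk MLE, daily smoother."""

import numpy as np
import pandas as pd
import pytest

from swimtrack import geodesy as geo
from swimtrack import ssm, synthetic


def _rw_fixes(seed=0, n=60, sigma=5.0, noise=1.0, days=20.0, aid="rw"):
    """Fixes from a known 2-D random walk with circular error of SD ``noise``."""
    rng = np.random.default_rng(seed)
    t = np.sort(rng.uniform(0, days, n))
    t[0] = 0.0
    dx = rng.normal(0, sigma * np.sqrt(np.diff(t)))
    dy = rng.normal(0, sigma * np.sqrt(np.diff(t)))
    x = np.r_[0, np.cumsum(dx)]
    y = np.r_[0, np.cumsum(dy)]
    ox = x + rng.normal(0, noise, n)
    oy = y + rng.normal(0, noise, n)
    fwd, inv = geo.local_plane(-81.0, 19.0)
    lon, lat = inv(ox, oy)
    return pd.DataFrame({
        "animal_id": aid,
        "time": pd.Timestamp("2022-01-22") + pd.to_timedelta(t, unit="D"),
        "lon": lon, "lat": lat,
        "smaj_km": noise, "smin_km": noise, "eor_deg": 0.0, "qclass": "1",
    }), (x, y, t)


class TestBufferFilter:
    def test_conservation_and_boundary(self):
        island = synthetic.island_polygon()
        c = island.centroid
        # one fix at ~exactly 10 km beyond the boundary, one inside, one far
        far_lon, far_lat = geo.displace(c.x, c.y, 300.0, 0.0)
        fixes = pd.DataFrame({
            "animal_id": ["a"] * 3,
            "time": pd.date_range("2022-01-22", periods=3, freq="h"),
            "lon": [c.x, far_lon, c.x],
            "lat": [c.y, far_lat, c.y + 0.01],
        })
        retained, report = ssm.buffer_filter(fixes, island, radius_km=10.0)
        assert report["n_removed"].iloc[0] + report["n_retained"].iloc[0] == 3
        assert len(retained) == 1

    def test_all_inside_flags_unusable(self):
        island = synthetic.island_polygon()
        c = island.centroid
        fixes = pd.DataFrame({"animal_id": ["a"] * 5,
                              "time": pd.date_range("2022-01-22", periods=5, freq="h"),
                              "lon": c.x, "lat": c.y})
        retained, report = ssm.buffer_filter(fixes, island)
        assert retained.empty
        assert not report["usable"].iloc[0]

    def test_fix_exactly_at_radius_retained(self):
        island = synthetic.island_polygon()
        c = island.centroid
        lon, lat = geo.displace(c.x, c.y, 0.0, 300.0)
        d = ssm.polygon_distance_km(lon, lat, island)
        # move the fix to land exactly at distance 10
        lon2, lat2 = geo.displace(lon, lat, 0.0, -(d - 10.0))
        d2 = ssm.polygon_distance_km(lon2, lat2, island)
        fixes = pd.DataFrame({"animal_id": ["a"], "time": [pd.Timestamp("2022-01-22")],
                              "lon": [lon2], "lat": [lat2]})
        retained, _ = ssm.buffer_filter(fixes, island, radius_km=min(d2, 10.0))
        assert len(retained) == 1

    def test_empty_polygon_rejected(self):
        from shapely.geometry import Polygon
        with pytest.raises(ValueError):
            ssm.buffer_filter(pd.DataFrame(), Polygon(), 10.0)


class TestFitRw:
    def test_too_few_fixes_rejected(self):
        fixes, _ = _rw_fixes(n=3)
        with pytest.raises(ValueError):
            ssm.fit_rw(fixes.iloc[:3])

    def test_single_day_span_rejected(self):
        fixes, _ = _rw_fixes(n=10, days=0.5)
        with pytest.raises(ValueError, match="two distinct days"):
            ssm.fit_rw(fixes)

    def test_zero_noise_matches_increment_mle(self):
        """With exact observations the Kalman MLE equals the closed-form
        variance-of-increments estimator of sigma_p."""
        fixes, (x, y, t) = _rw_fixes(seed=3, n=80, sigma=4.0, noise=0.0)
        fixes["smaj_km"] = 1e-9
        fixes["smin_km"] = 1e-9
        fit = ssm.fit_rw(fixes)
        # closed form evaluated in the same tangent plane the filter uses
        times, z, _, _ = ssm._fix_arrays(fixes)
        dt = np.diff(times)
        closed = np.sqrt(np.sum((np.diff(z[:, 0]) ** 2 + np.diff(z[:, 1]) ** 2) / dt)
                         / (2 * (len(times) - 1)))
        assert fit.sigma_p == pytest.approx(closed, rel=1e-4)

    def test_likelihood_local_maximum(self):
        fixes, _ = _rw_fixes(seed=5, n=60, sigma=5.0, noise=1.0)
        fit = ssm.fit_rw(fixes)
        times, z, covs, _ = ssm._fix_arrays(fixes)
        ll_hat = ssm._kalman(times, z, covs, fit.sigma_p)
        assert ll_hat >= ssm._kalman(times, z, covs, 0.5 * fit.sigma_p)
        assert ll_hat >= ssm._kalman(times, z, covs, 2.0 * fit.sigma_p)

    def test_recovery_across_seeds(self):
        """sigma_p within 20% of truth in most replicates (reduced-size
        version of the full Monte-Carlo run in the acceptance suite)."""
        hits = 0
        for seed in range(10):
            fixes, _ = _rw_fixes(seed=seed, n=200, sigma=5.0, noise=1.0, days=40)
            fit = ssm.fit_rw(fixes)
            hits += abs(fit.sigma_p - 5.0) / 5.0 < 0.2
        assert hits >= 9


class TestSmoothDaily:
    def test_two_exact_fixes_bridge_is_linear(self):
        fixes = pd.DataFrame({
            "animal_id": "a",
            "time": pd.to_datetime(["2022-01-22", "2022-01-24"]),
            "lon": [-81.0, -81.0], "lat": [19.0, 19.4],
            "smaj_km": 1e-9, "smin_km": 1e-9, "eor_deg": 0.0, "qclass": "3"})
        fit = ssm.RwFit("a", 5.0, 0.0, True, 2, -81.0, 19.2)
        track = ssm.smooth_daily(fixes, fit)
        err = geo.great_circle_km(track["lon"].iloc[1], track["lat"].iloc[1],
                                  -81.0, 19.2)
        assert err < 1e-6

    def test_single_fix_degenerate_track(self):
        fixes = pd.DataFrame({"animal_id": "a", "time": [pd.Timestamp("2022-01-22")],
                              "lon": [-81.0], "lat": [19.0], "smaj_km": [1.0],
                              "smin_km": [1.0], "eor_deg": [0.0], "qclass": ["1"]})
        fit = ssm.RwFit("a", 5.0, 0.0, True, 1, -81.0, 19.0)
        track = ssm.smooth_daily(fixes, fit)
        assert len(track) == 1 and track["lon"].iloc[0] == -81.0

    def test_smoother_passes_through_near_exact_fix(self):
        fixes, _ = _rw_fixes(seed=8, n=40, noise=2.0)
        fixes.loc[20, ["smaj_km", "smin_km"]] = 1e-9
        fit = ssm.fit_rw(fixes)
        times, z, covs, (lon0, lat0, fwd, inv) = ssm._fix_arrays(fixes)
        ll, sm, sP, all_t, is_obs, src = ssm._kalman(times, z, covs, fit.sigma_p,
                                                     smooth=True)
        k = np.flatnonzero(is_obs)[20]
        assert np.hypot(*(sm[k] - z[20])) < 1e-6

    def test_sd_grows_inside_gap(self):
        """Predicted SD is unimodal within an observation gap."""
        fixes = pd.DataFrame({
            "animal_id": "a",
            "time": pd.to_datetime(["2022-01-22", "2022-01-28"]),
            "lon": [-81.0, -80.5], "lat": [19.0, 19.4],
            "smaj_km": 0.1, "smin_km": 0.1, "eor_deg": 0.0, "qclass": "3"})
        fit = ssm.RwFit("a", 5.0, 0.0, True, 2, -81.0, 19.2)
        track = ssm.smooth_daily(fixes, fit)
        sd = track["sd_km"].to_numpy()
        peak = np.argmax(sd)
        assert np.all(np.diff(sd[: peak + 1]) >= -1e-9)
        assert np.all(np.diff(sd[peak:]) <= 1e-9)

    def test_grid_truncated_past_last_fix(self):
        fixes, _ = _rw_fixes(seed=9, n=20, days=5.0)
        fit = ssm.fit_rw(fixes)
        track = ssm.smooth_daily(fixes, fit, n_days=30)
        span = (pd.to_datetime(fixes["time"].iloc[-1])
                - pd.to_datetime(fixes["time"].iloc[0])) / pd.Timedelta(days=1)
        last = (track["date"].iloc[-1] - track["date"].iloc[0]) / pd.Timedelta(days=1)
        assert last <= span + 3.0

    def test_smoothing_beats_nearest_raw_fix(self):
        """RMSE of smoothed daily positions vs truth is below the RMSE of
        simply taking the nearest raw fix."""
        f = synthetic.build_field(synthetic.CurrentFieldSpec(
            kind="uniform", u0=0.1, v0=0.05, days=14, resolution_deg=0.5), seed=0)
        spec = synthetic.SwimmerSpec(release=(-81, 18.5), goal=(-78, 21),
                                     duration_days=10.0)
        fine = synthetic.simulate_swimmer(spec, f, seed=4)
        noise = synthetic.ArgosNoiseSpec(fixes_per_day_mean=6.0)
        fixes = synthetic.observe_argos(fine, noise, seed=5)
        fit = ssm.fit_rw(fixes)
        track = ssm.smooth_daily(fixes, fit)
        tt = (fine["time"] - fine["time"].iloc[0]) / pd.Timedelta(days=1)
        ft = (fixes["time"] - fine["time"].iloc[0]) / pd.Timedelta(days=1)
        e_smooth, e_raw = [], []
        for _, row in track.iterrows():
            g = (row["date"] - fine["time"].iloc[0]) / pd.Timedelta(days=1)
            lon_t = np.interp(g, tt, fine["lon"])
            lat_t = np.interp(g, tt, fine["lat"])
            e_smooth.append(geo.great_circle_km(row["lon"], row["lat"], lon_t, lat_t))
            j = np.argmin(np.abs(ft - g))
            e_raw.append(geo.great_circle_km(fixes["lon"].iloc[j], fixes["lat"].iloc[j],
                                             lon_t, lat_t))
        assert np.sqrt(np.mean(np.square(e_smooth))) < np.sqrt(np.mean(np.square(e_raw)))


class TestOverinterpolation:
    def test_gap_free_track_empty_report(self):
        fixes, _ = _rw_fixes(seed=10, n=40, days=10.0)
        fit = ssm.fit_rw(fixes)
        track = ssm.smooth_daily(fixes, fit)
        rep = ssm.overinterpolation_report(fixes, track)
        assert rep.empty

    def test_long_gap_bridge_flagged_straight(self):
        fixes = pd.DataFrame({
            "animal_id": "a",
            "time": pd.to_datetime(["2022-01-22", "2022-01-23", "2022-01-28",
                                    "2022-01-29"]),
            "lon": [-81.0, -80.9, -80.4, -80.3], "lat": [19.0, 19.1, 19.6, 19.7],
            "smaj_km": 1e-6, "smin_km": 1e-6, "eor_deg": 0.0, "qclass": "3"})
        fit = ssm.RwFit("a", 5.0, 0.0, True, 4, -81, 19)
        track = ssm.smooth_daily(fixes, fit)
        rep = ssm.overinterpolation_report(fixes, track)
        assert len(rep) == 1
        assert rep["straightness"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert bool(rep["flagged"].iloc[0])
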