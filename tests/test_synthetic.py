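"""Synthetic world generator: fields, swimmers, drifters, ARGOS noise, cohorts."""

import numpy as np
import pandas as pd
import pytest

from swimtrack import geodesy as geo
from swimtrack import synthetic as syn


class TestBuildField:
    def test_uniform_cells(self, uniform_field):
        ds = uniform_field.dataset
        assert np.allclose(ds["u"].values, 0.3)
        assert np.allclose(ds["v"].values, 0.0)

    def test_vortex_center_and_ring(self, vortex_field):
        u, v = vortex_field.current_at(-81.0, 19.5)
        assert np.hypot(u, v) < 1e-9
        # at the core radius the tangential speed equals the peak
        lon_r, lat_r = geo.displace(-81.0, 19.5, 100.0, 0.0)
        u, v = vortex_field.current_at(lon_r, lat_r)
        assert np.hypot(u, v) == pytest.approx(0.5, rel=1e-6)
        # east of a clockwise vortex the flow is southward
        assert v < 0

    def test_vortex_curl_is_clockwise(self, vortex_field):
        """Finite-difference curl (dv/dx - du/dy) is negative inside the
        core of a clockwise (anticyclonic-rotation) vortex."""
        h = 0.01
        for dx, dy in [(30, 0), (0, 40), (-25, 25), (-10, -60)]:
            lon, lat = geo.displace(-81.0, 19.5, dx, dy)
            u1, _ = vortex_field.current_at(lon, lat - h)
            u2, _ = vortex_field.current_at(lon, lat + h)
            _, v1 = vortex_field.current_at(lon - h, lat)
            _, v2 = vortex_field.current_at(lon + h, lat)
            km = geo.KM_PER_DEG
            curl = ((v2 - v1) / (2 * h * km * np.cos(np.radians(lat)))
                    - (u2 - u1) / (2 * h * km))
            assert curl < 0

    def test_sst_and_sargassum_bounds(self, vortex_field):
        ds = vortex_field.dataset
        assert float(ds["sst"].min()) >= 20.0
        assert float(ds["sst"].max()) <= 33.0
        assert float(ds["sargassum"].min()) >= 0.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            syn.CurrentFieldSpec(lon_range=(-80.0, -80.0))


class TestSimulateSwimmer:
    def test_straight_meridian_track(self):
        f = syn.build_field(syn.CurrentFieldSpec(kind="uniform", u0=0, v0=0, days=8,
                                                 resolution_deg=0.5), seed=0)
        spec = syn.SwimmerSpec(release=(-81, 18), goal=(-81, 22.5),
                               mean_swim_kmday=30.0, speed_cv=0.0, kappa=1e6,
                               duration_days=5.0)
        tr = syn.simulate_swimmer(spec, f, seed=1)
        assert np.allclose(tr["lon"], -81.0, atol=1e-6)
        d = geo.great_circle_km(tr["lon"].iloc[0], tr["lat"].iloc[0],
                                tr["lon"].iloc[-1], tr["lat"].iloc[-1])
        assert d == pytest.approx(150.0, rel=1e-3)

    def test_zero_swim_is_pure_drifter(self, uniform_field):
        tr = syn.simulate_drifter((-81, 19), uniform_field, duration_days=1.0, seed=0)
        d = geo.great_circle_km(tr["lon"].iloc[0], tr["lat"].iloc[0],
                                tr["lon"].iloc[-1], tr["lat"].iloc[-1])
        assert d == pytest.approx(0.3 * 86.4, rel=1e-3)
        assert tr["lat"].iloc[-1] == pytest.approx(19.0, abs=1e-6)

    def test_zero_field_drifter_stationary(self):
        f = syn.build_field(syn.CurrentFieldSpec(kind="uniform", u0=0, v0=0, days=3,
                                                 resolution_deg=0.5), seed=0)
        tr = syn.simulate_drifter((-81, 19), f, duration_days=1.0, seed=0)
        assert np.allclose(tr["lon"], -81.0) and np.allclose(tr["lat"], 19.0)

    def test_vortex_orbit_roughly_circular(self, vortex_field):
        """A drifter released at the core radius orbits with small radius drift."""
        lon0, lat0 = geo.displace(-81.0, 19.5, 100.0, 0.0)
        # period of the core-radius orbit: 2 pi r / v
        period_days = 2 * np.pi * 100.0 / (0.5 * 86.4)
        tr = syn.simulate_drifter((lon0, lat0), vortex_field,
                                  duration_days=period_days, seed=0,
                                  dt_days=0.002)
        fwd, _ = geo.local_plane(-81.0, 19.5)
        x, y = fwd(tr["lon"].to_numpy(), tr["lat"].to_numpy())
        r = np.hypot(x, y)
        assert abs(r[-1] - r[0]) / r[0] < 0.02
        assert r.max() / r.min() < 1.05

    def test_ground_equals_swim_plus_current_by_construction(self, small_cohort):
        fine = small_cohort["truth"]
        one = fine[fine["animal_id"] == fine["animal_id"].iloc[0]].reset_index(drop=True)
        # integrate one step by hand and compare with the recorded position
        i = 10
        lon2, lat2 = geo.displace(one["lon"][i], one["lat"][i],
                                  one["swim_east"][i] + one["cur_east"][i],
                                  one["swim_north"][i] + one["cur_north"][i], 0.05)
        assert lon2 == pytest.approx(one["lon"][i + 1], abs=1e-12)
        assert lat2 == pytest.approx(one["lat"][i + 1], abs=1e-12)


class TestObserveArgos:
    def test_zero_ellipse_on_track(self):
        f = syn.build_field(syn.CurrentFieldSpec(kind="uniform", u0=0.1, v0=0.1,
                                                 days=6, resolution_deg=0.5), seed=0)
        tr = syn.simulate_swimmer(syn.SwimmerSpec(duration_days=4.0), f, seed=1)
        spec = syn.ArgosNoiseSpec(class_smaj_km={c: 1e-12 for c in "3210AB"})
        fx = syn.observe_argos(tr, spec, seed=2)
        tt = (tr["time"] - tr["time"].iloc[0]) / pd.Timedelta(days=1)
        for _, r in fx.iterrows():
            ft = (r["time"] - tr["time"].iloc[0]) / pd.Timedelta(days=1)
            lon = np.interp(ft, tt, tr["lon"])
            lat = np.interp(ft, tt, tr["lat"])
            assert geo.great_circle_km(r["lon"], r["lat"], lon, lat) < 1e-6

    def test_fix_times_strictly_increasing(self, small_cohort):
        for _, sub in small_cohort["fixes"].groupby("animal_id"):
            assert sub["time"].is_monotonic_increasing

    def test_daily_count_matches_negative_binomial_mean(self):
        f = syn.build_field(syn.CurrentFieldSpec(kind="uniform", days=110,
                                                 resolution_deg=0.5), seed=0)
        tr = syn.simulate_drifter((-81, 19), f, duration_days=100.0, seed=0,
                                  dt_days=0.05)
        spec = syn.ArgosNoiseSpec(fixes_per_day_mean=12.6, fixes_per_day_dispersion=4.0)
        fx = syn.observe_argos(tr, spec, seed=3)
        mean = len(fx) / 100.0
        # negative binomial: var = mu + mu^2/size; SE of 100-day mean
        var = 12.6 + 12.6**2 / 4.0
        se = np.sqrt(var / 100)
        assert abs(mean - 12.6) < 3 * se

    def test_empirical_error_covariance_matches_ellipse(self):
        """Monte-Carlo check of the ellipse noise model at n = 10^4."""
        rng = np.random.default_rng(0)
        smaj, smin, ori = 3.0, 1.5, 30.0
        draws = np.array([syn._ellipse_noise(rng, smaj, smin, ori) for _ in range(10_000)])
        emp = np.cov(draws.T)
        want = syn.ellipse_cov(smaj, smin, ori)
        assert np.allclose(emp, want, rtol=0.1, atol=0.15)

    def test_ellipse_cov_axes(self):
        c = syn.ellipse_cov(2.0, 1.0, 0.0)  # major axis due north
        assert c[1, 1] == pytest.approx(4.0)
        assert c[0, 0] == pytest.approx(1.0)
        assert c[0, 1] == pytest.approx(0.0, abs=1e-12)


class TestMakeCohort:
    def test_residential_count_and_agreement(self):
        coh = syn.make_cohort("jan", 30, seed=5)
        cov = coh["covariates"]
        assert int(cov["residential_truth"].sum()) == 16

    def test_degenerate_single_animal(self):
        coh = syn.make_cohort("jul", 1, seed=0, duration_days=5.0)
        assert coh["covariates"].shape[0] == 1
        assert len(coh["fixes"]) > 0

    def test_jan_goal_bearings_span_quadrants(self):
        coh = syn.make_cohort("jan", 30, seed=2, duration_days=3.0)
        brg = coh["covariates"]["goal_bearing_deg"].dropna().to_numpy()
        quadrants = set((brg // 90).astype(int))
        assert len(quadrants) >= 3

    def test_identical_seeds_identical_cohorts(self):
        a = syn.make_cohort("jul", 4, seed=9, duration_days=4.0)
        b = syn.make_cohort("jul", 4, seed=9, duration_days=4.0)
        pd.testing.assert_frame_equal(a["fixes"], b["fixes"])
        pd.testing.assert_frame_equal(a["truth"], b["truth"])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            syn.make_cohort("jan", 0)
        with pytest.raises(ValueError):
            syn.make_cohort("spring", 5)


class TestPersistenceDataset:
    def test_known_structure(self):
        df, truth = syn.make_persistence_dataset(n_animals=6, n_days=8, seed=0)
        assert len(df) == 48
        assert set(df["period"]) == {"jan", "jul"}
        assert truth["period_effect"] == 6.2

    def test_surface_applied(self):
        df, _ = syn.make_persistence_dataset(n_animals=4, n_days=5, seed=1,
                                             period_effect=0.0, innovation_sd=0.0,
                                             animal_sd=0.0, ar1=0.0,
                                             surface=lambda la, lo: 100.0)
        assert np.allclose(df["persistence"], 100.0 - 0.7)
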