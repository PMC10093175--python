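"""Persistence mixed model: basis, penalized fit, ARMA selection, elimination."""

import numpy as np
import pandas as pd
import pytest

from swimtrack import gamm, synthetic


@pytest.fixture(scope="module")
def small_series():
    df, _ = synthetic.make_persistence_dataset(n_animals=10, n_days=12, seed=3)
    return df


class TestSmoothBasis:
    def test_design_shape_and_rank(self, small_series):
        spec = gamm.GammSpec(fixed_effects=("period",), k=12)
        des = gamm.build_design(small_series, spec)
        n = len(small_series)
        assert des.X.shape[0] == n
        assert des.pen_mask.sum() == des.basis.n_penalized
        # unpenalized block has full column rank
        unpen = des.X[:, ~des.pen_mask]
        assert np.linalg.matrix_rank(unpen) == unpen.shape[1]

    def test_duplicate_locations_identical_rows(self, small_series):
        spec = gamm.GammSpec(fixed_effects=(), k=10)
        des = gamm.build_design(small_series, spec)
        B1 = des.basis.design(np.array([19.0, 19.0]), np.array([-81.0, -81.0]))
        np.testing.assert_allclose(B1[0], B1[1])

    def test_linear_surface_reproduced_exactly(self):
        """The unpenalized null space captures any a + b*lat + c*lon."""
        rng = np.random.default_rng(0)
        df, _ = synthetic.make_persistence_dataset(
            n_animals=8, n_days=10, seed=2, period_effect=0.0, innovation_sd=0.0,
            animal_sd=0.0, ar1=0.0, surface=lambda la, lo: 3.0 + 2.0 * la - 1.5 * lo)
        spec = gamm.GammSpec(fixed_effects=(), k=12, random_intercept=False)
        fit = gamm.fit(df, spec)
        assert np.abs(fit.residuals).max() < 1e-8

    def test_k_too_small_rejected(self):
        with pytest.raises(ValueError):
            gamm.GammSpec(k=2)


class TestArmaCov:
    def test_acovf_matches_statsmodels(self):
        from statsmodels.tsa.arima_process import arma_acovf
        for ar, ma in [([0.5], []), ([], [0.4]), ([0.6, -0.3], [0.2, 0.1])]:
            mine = gamm._arma_acovf(np.array(ar), np.array(ma), 12, 1.7)
            ref = arma_acovf(np.r_[1, -np.array(ar)], np.r_[1, np.array(ma)],
                             nobs=12, sigma2=1.7)
            np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_animal_cov_structure(self):
        V = gamm._animal_cov([3, 2], 0.5, np.array([0.5]), np.empty(0), 1.0)
        # random intercept couples the two runs; ARMA does not
        assert V[0, 4] == pytest.approx(0.5)
        assert V[0, 1] > V[0, 4]


class TestFit:
    def test_reduces_to_penalized_least_squares(self, small_series):
        """ARMA(0,0), no random effect: identical to the direct PLS oracle."""
        spec = gamm.GammSpec(fixed_effects=("period", "sst"), k=12,
                             arma=(0, 0), random_intercept=False)
        f = gamm.fit(small_series, spec)
        des = f.design
        P = np.diag(des.pen_mask.astype(float))
        beta = np.linalg.solve(des.X.T @ des.X / f.sigma**2 + f.lam * P,
                               des.X.T @ des.y / f.sigma**2)
        assert np.abs(beta - f.beta).max() < 1e-6

    def test_deterministic(self, small_series):
        spec = gamm.GammSpec(fixed_effects=("period",), k=10, arma=(1, 0))
        f1 = gamm.fit(small_series, spec)
        f2 = gamm.fit(small_series, spec)
        assert f1.aic == f2.aic
        np.testing.assert_array_equal(f1.beta, f2.beta)

    def test_pure_noise_smoother_shrinks(self):
        """Under pure noise the penalized smoother EDF collapses and slopes
        stay within 2 SE of zero (small-rep version)."""
        edfs, cover = [], 0
        for seed in range(5):
            df, _ = synthetic.make_persistence_dataset(
                n_animals=10, n_days=12, seed=seed, period_effect=0.0,
                ar1=0.0, animal_sd=0.5)
            f = gamm.fit(df, gamm.GammSpec(fixed_effects=("sst",), k=12,
                                           random_intercept=True, arma=(0, 0)))
            edfs.append(f.smooth_edf)
            cover += abs(f.coef["sst"]) <= 2 * f.se["sst"]
        assert np.median(edfs) < 2.0
        assert cover >= 4

    def test_ar1_recovered(self):
        df, truth = synthetic.make_persistence_dataset(n_animals=15, n_days=15,
                                                       seed=4, ar1=0.5)
        f = gamm.fit(df, gamm.GammSpec(fixed_effects=("period",), k=10, arma=(1, 0)))
        assert f.ar[0] == pytest.approx(0.5, abs=0.2)

    def test_surface_recovery(self):
        """A smooth bowl is recovered with small RMSE relative to its range."""
        bowl = lambda la, lo: 0.6 * ((la - 19.5) ** 2 + 0.5 * (lo + 81.0) ** 2)
        df, _ = synthetic.make_persistence_dataset(
            n_animals=25, n_days=14, seed=6, period_effect=0.0,
            innovation_sd=1.0, animal_sd=0.0, ar1=0.0, surface=bowl)
        f = gamm.fit(df, gamm.GammSpec(fixed_effects=(), k=25,
                                       random_intercept=False, arma=(0, 0)))
        true_vals = bowl(df["lat"].to_numpy(), df["lon"].to_numpy())
        # compare centred surfaces (intercept absorbs the level)
        pred = f.fitted - f.fitted.mean()
        truth_c = true_vals - true_vals.mean()
        rmse = np.sqrt(np.mean((pred - truth_c) ** 2))
        assert rmse < 0.15 * np.ptp(truth_c)
        r = np.corrcoef(pred, truth_c)[0, 1]
        assert r > 0.9


class TestSelectArma:
    def test_white_noise_picks_00(self):
        rng = np.random.default_rng(0)
        hits = 0
        for rep in range(10):
            series = [rng.normal(0, 1, 15) for _ in range(20)]
            (p, q), _ = gamm.select_arma(series)
            hits += (p, q) == (0, 0)
        assert hits >= 9

    def test_ar_process_detected(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(10):
            series = []
            for _ in range(20):
                e = np.zeros(15)
                for t in range(1, 15):
                    e[t] = 0.7 * e[t - 1] + rng.normal()
                series.append(e)
            (p, q), _ = gamm.select_arma(series)
            hits += p >= 1
        assert hits >= 9

    def test_deterministic_and_short_series_note(self):
        rng = np.random.default_rng(2)
        series = [rng.normal(0, 1, 30) for _ in range(5)]
        a = gamm.select_arma(series)
        b = gamm.select_arma(series)
        assert a[0] == b[0]
        (pq, table) = gamm.select_arma([np.ones(3)])
        assert pq == (0, 0) and "note" in table.columns


class TestBackwardElimination:
    def test_single_strong_candidate_retained(self):
        df, _ = synthetic.make_persistence_dataset(n_animals=12, n_days=12,
                                                   seed=8, period_effect=10.0,
                                                   innovation_sd=3.0, ar1=0.0)
        spec = gamm.GammSpec(fixed_effects=("period",), k=10, arma=(0, 0))
        final, trace = gamm.backward_eliminate(df, spec)
        assert final.spec.fixed_effects == ("period",)
        assert final.method == "REML"

    def test_strict_rule_aic_monotone(self, small_series):
        spec = gamm.GammSpec(fixed_effects=("period", "sst", "cur_speed"),
                             k=10, arma=(0, 0))
        final, trace = gamm.backward_eliminate(small_series, spec,
                                               aic_tolerance=0.0)
        aics = trace["aic"].to_numpy()
        assert np.all(np.diff(aics) < 0)  # every accepted drop lowered AIC

    def test_trace_records_path(self, small_series):
        spec = gamm.GammSpec(fixed_effects=("period", "sst"), k=10, arma=(0, 0))
        final, trace = gamm.backward_eliminate(small_series, spec)
        assert trace["step"].iloc[0] == 0
        assert set(trace.columns) >= {"step", "dropped", "kept", "aic"}


class TestPredict:
    def test_training_rows_equal_fitted(self, small_series):
        spec = gamm.GammSpec(fixed_effects=("period",), k=10,
                             arma=(0, 0), random_intercept=False)
        f = gamm.fit(small_series, spec)
        pr = gamm.predict(f, small_series)
        np.testing.assert_allclose(pr["mean"].to_numpy(), f.fitted, atol=1e-8)

    def test_intercept_only_constant_prediction(self):
        df, _ = synthetic.make_persistence_dataset(n_animals=6, n_days=10, seed=9,
                                                   period_effect=0.0)
        spec = gamm.GammSpec(fixed_effects=(), k=10, random_intercept=False,
                             arma=(0, 0))
        f = gamm.fit(df, spec)
        grid = gamm.prediction_grid(f, n=5)
        # heavy smoothing under the null keeps the surface nearly flat
        assert np.ptp(grid["mean"]) < np.ptp(f.design.y)

    def test_summary_table_layout(self, small_series):
        f = gamm.fit(small_series, gamm.GammSpec(fixed_effects=("period",), k=10))
        tab = f.summary_table()
        assert {"term", "estimate", "se", "p"} <= set(tab.columns)
        assert "s(lat,lon)" in set(tab["term"])
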