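"""Additive mixed model for daily swimming persistence.

Model.  For animal i on day t,

    V_it = beta0 + x_it' beta + f(lat_it, lon_it) + b_i + e_it

where V is the daily persistence velocity (km/day), x are candidate
linear covariates (current speed, SST, sargassum density, body weight,
tracking period), f is a penalized thin-plate-style radial smoother of
location, b_i ~ N(0, tau^2) is a per-animal random intercept, and e_it
follows a zero-mean Gaussian ARMA(p, q) process on the daily grid.

Estimation alternates (a) penalized generalized least squares for the
mean structure, with the smoothing parameter chosen by GCV on the
whitened problem, and (b) maximum likelihood for the variance
parameters (tau, the ARMA coefficients and innovation SD) given the
mean, iterating to convergence of the marginal AIC.  The random
intercept and the ARMA process live in the marginal covariance of each
animal's residual series, so with tau = 0 and ARMA(0, 0) the whole
procedure collapses to ordinary penalized least squares.

Model selection follows the standard mixed-model recipe: backward
elimination of fixed effects by AIC under ML, the smoother and random
intercept never dropped, final refit under REML.  ARMA orders are
selected on the residual series via an ACF/PACF-seeded grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular, toeplitz
from scipy.optimize import minimize, minimize_scalar
from statsmodels.tsa.arima_process import arma_acovf
from statsmodels.tsa.statespace.tools import (
    constrain_stationary_univariate as _constrain,
    unconstrain_stationary_univariate as _unconstrain,
)
from statsmodels.tsa.stattools import acf as _acf, pacf as _pacf

CANDIDATE_ORDER = ("cur_speed", "sst", "sargassum", "weight_kg", "period")


@dataclass
class GammSpec:
    """Model structure: candidate fixed effects, smoother size, error process."""

    fixed_effects: tuple = CANDIDATE_ORDER
    k: int = 30                      # smoother basis dimension (knot count)
    random_intercept: bool = True
    arma: tuple = (0, 0)             # (p, q)
    method: str = "ML"               # ML | REML

    def __post_init__(self):
        if self.k < 3:
            raise ValueError("smoother needs k >= 3")
        p, q = self.arma
        if p < 0 or q < 0 or p > 6 or q > 6:
            raise ValueError("ARMA orders must be in 0..6")


# ---------------------------------------------------------------- smoother


def _eta(r):
    """Thin-plate radial basis function in 2-D: r^2 log r (0 at r = 0)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r * r * np.log(r)
    return np.where(r > 0, out, 0.0)


def _farthest_point_knots(pts, k, seed=0):
    """Deterministic farthest-point subsample of unique locations."""
    uniq = np.unique(pts, axis=0)
    if len(uniq) <= k:
        return uniq
    # start from the point closest to the centroid for determinism
    c = uniq.mean(axis=0)
    idx = [int(np.argmin(((uniq - c) ** 2).sum(axis=1)))]
    d = ((uniq - uniq[idx[0]]) ** 2).sum(axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, ((uniq - uniq[nxt]) ** 2).sum(axis=1))
    return uniq[np.array(idx)]


@dataclass
class SmoothBasis:
    knots: np.ndarray          # (k, 2) scaled coordinates
    center: np.ndarray
    scale: np.ndarray
    transform: np.ndarray      # (k, m) maps knot weights -> whitened penalized coords

    def design(self, lat, lon):
        """Columns [lat_s, lon_s, penalized...] for given coordinates."""
        pts = self._scaled(lat, lon)
        d = np.sqrt(((pts[:, None, :] - self.knots[None, :, :]) ** 2).sum(-1))
        C = _eta(d) @ self.transform
        return np.column_stack([pts[:, 0], pts[:, 1], C])

    def _scaled(self, lat, lon):
        pts = np.column_stack([np.asarray(lat, float), np.asarray(lon, float)])
        return (pts - self.center) / self.scale

    @property
    def n_penalized(self):
        return self.transform.shape[1]


def make_smooth_basis(lat, lon, k=30):
    """Low-rank thin-plate-style basis with an identity penalty.

    Knots are a farthest-point subsample of the observed locations; the
    side condition removing the polynomial null space from the radial
    part is absorbed so that the returned penalized block has penalty
    lambda * I.  The unpenalized null space (linear in lat and lon) is
    exposed as the first two columns; the global intercept lives with
    the fixed effects.
    """
    pts = np.column_stack([np.asarray(lat, float), np.asarray(lon, float)])
    center = pts.mean(axis=0)
    scale = pts.std(axis=0)
    scale[scale == 0] = 1.0
    sp = (pts - center) / scale
    knots = _farthest_point_knots(sp, k)
    kk = len(knots)
    E = _eta(np.sqrt(((knots[:, None, :] - knots[None, :, :]) ** 2).sum(-1)))
    T = np.column_stack([np.ones(kk), knots])
    U, _, _ = np.linalg.svd(T, full_matrices=True)
    Z = U[:, T.shape[1]:]                       # null space of T'
    S = Z.T @ E @ Z
    S = 0.5 * (S + S.T)
    w, Q = np.linalg.eigh(S)
    keep = w > max(w.max(), 1.0) * 1e-10
    M = Z @ Q[:, keep] / np.sqrt(w[keep])       # whitens the penalty to I
    return SmoothBasis(knots=knots, center=center, scale=scale, transform=M)


# ---------------------------------------------------------------- design


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray                 # full design: fixed | lat | lon | penalized
    pen_mask: np.ndarray          # bool per column
    col_names: list
    basis: SmoothBasis
    animal_ids: np.ndarray        # per retained row
    runs: list                    # [(animal, [contiguous index arrays])]
    n_dropped: int
    period_levels: list
    notes: list = dc_field(default_factory=list)


def build_design(series: pd.DataFrame, spec: GammSpec) -> Design:
    """Complete-case design matrices for a persistence-series table.

    ``series`` needs columns animal_id, date, lat, lon, persistence and
    whichever candidate covariates the spec retains.  The tracking
    period enters as a two-level indicator (first level alphabetically,
    i.e. "jan", with the later level as reference); a single observed
    level drops the column with a note.
    """
    notes = []
    df = series.sort_values(["animal_id", "date"], kind="stable").reset_index(drop=True)
    cols = ["persistence", "lat", "lon"] + [c for c in spec.fixed_effects if c != "period"]
    if "period" in spec.fixed_effects:
        cols.append("period")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"series table lacks columns {missing}")
    ok = np.ones(len(df), bool)
    for c in cols:
        if c == "period":
            ok &= df[c].notna().to_numpy()
        else:
            ok &= np.isfinite(pd.to_numeric(df[c], errors="coerce").to_numpy())
    kept = df.loc[ok].reset_index(drop=True)
    n_dropped = int((~ok).sum())

    y = kept["persistence"].to_numpy(dtype=float)
    blocks = [np.ones((len(kept), 1))]
    names = ["intercept"]
    period_levels = []
    for c in spec.fixed_effects:
        if c == "period":
            period_levels = sorted(kept["period"].astype(str).unique())
            if len(period_levels) < 2:
                notes.append("period has a single level; column dropped")
                continue
            ind = (kept["period"].astype(str) == period_levels[0]).to_numpy(float)
            blocks.append(ind[:, None])
            names.append(f"period[{period_levels[0]}]")
        else:
            col = kept[c].to_numpy(dtype=float)
            if np.ptp(col) == 0:
                notes.append(f"{c} is constant after complete-case filtering; dropped")
                continue
            blocks.append(col[:, None])
            names.append(c)
    basis = make_smooth_basis(kept["lat"], kept["lon"], k=spec.k)
    B = basis.design(kept["lat"].to_numpy(), kept["lon"].to_numpy())
    names += ["s(lat)", "s(lon)"] + [f"s.{i}" for i in range(basis.n_penalized)]
    X = np.column_stack(blocks + [B])
    pen_mask = np.zeros(X.shape[1], bool)
    pen_mask[-basis.n_penalized:] = True

    # contiguous daily runs per animal (gaps break the ARMA recursion)
    runs = []
    ids = kept["animal_id"].to_numpy()
    dates = pd.to_datetime(kept["date"]).to_numpy()
    for aid in pd.unique(ids):
        ii = np.flatnonzero(ids == aid)
        gaps = np.flatnonzero(np.diff(dates[ii]) / np.timedelta64(1, "D") > 1.5)
        pieces = np.split(ii, gaps + 1)
        runs.append((aid, [p for p in pieces]))
    return Design(y=y, X=X, pen_mask=pen_mask, col_names=names, basis=basis,
                  animal_ids=ids, runs=runs, n_dropped=n_dropped,
                  period_levels=period_levels, notes=notes)


# ---------------------------------------------------------------- variance


def _arma_acovf(ar, ma, n, sigma2, tail=256):
    """Stationary ARMA autocovariance via the MA(infinity) psi-weights.

    psi_0 = 1, psi_j = theta_j + sum_i phi_i psi_{j-i}; gamma_k =
    sigma2 * sum_j psi_j psi_{j+k}.  The expansion is truncated ``tail``
    terms past the needed lags, ample for the stationarity-constrained
    coefficients used here.  (Cross-checked against statsmodels'
    arma_acovf in the test suite.)
    """
    from scipy.signal import lfilter
    J = n + tail
    imp = np.zeros(J)
    imp[0] = 1.0
    psi = lfilter(np.r_[1.0, ma], np.r_[1.0, -np.asarray(ar)], imp)
    g = np.correlate(psi, psi, "full")[J - 1: J - 1 + n]
    return sigma2 * g


def _arma_cov(n, ar, ma, sigma2):
    if len(ar) == 0 and len(ma) == 0:
        return sigma2 * np.eye(n)
    return toeplitz(_arma_acovf(np.asarray(ar, float), np.asarray(ma, float),
                                n, sigma2))


def _animal_cov(run_lengths, tau2, ar, ma, sigma2):
    """Marginal covariance of one animal: tau^2 J + blockdiag(ARMA runs)."""
    n = sum(run_lengths)
    V = np.full((n, n), tau2)
    off = 0
    for m in run_lengths:
        V[off:off + m, off:off + m] += _arma_cov(m, ar, ma, sigma2)
        off += m
    return V


class _VarModel:
    """Packs/unpacks the variance parameters and evaluates the likelihood."""

    def __init__(self, design: Design, p, q, random_intercept):
        self.p, self.q = p, q
        self.ri = random_intercept
        self.signatures = []
        for aid, pieces in design.runs:
            self.signatures.append(tuple(len(x) for x in pieces))
        self.uniq = sorted(set(self.signatures))

    def pack(self, tau, sigma, ar, ma):
        parts = []
        if self.ri:
            parts.append(np.log(max(tau, 1e-6)))
        parts.append(np.log(max(sigma, 1e-6)))
        if self.p:
            parts.extend(_unconstrain(np.asarray(ar, float)))
        if self.q:
            parts.extend(_unconstrain(-np.asarray(ma, float)))
        return np.array(parts)

    def unpack(self, params):
        params = np.asarray(params, float)
        i = 0
        tau = 0.0
        if self.ri:
            tau = float(np.exp(np.clip(params[i], -12, 12)))
            i += 1
        sigma = float(np.exp(np.clip(params[i], -12, 12)))
        i += 1
        ar = _constrain(params[i:i + self.p]) if self.p else np.empty(0)
        i += self.p
        ma = -_constrain(params[i:i + self.q]) if self.q else np.empty(0)
        return tau, sigma, ar, ma

    def chols(self, params):
        """Cholesky factor of V per unique run-length signature."""
        tau, sigma, ar, ma = self.unpack(params)
        out = {}
        for sig in self.uniq:
            V = _animal_cov(sig, tau**2, ar, ma, sigma**2)
            out[sig] = np.linalg.cholesky(V)
        return out

    def negloglik(self, params, resid_groups):
        """resid_groups: list of (signature, residual-vector) per animal.

        Animals sharing a run-length signature share the covariance, so
        their residuals are stacked and whitened with one triangular
        solve.
        """
        try:
            Ls = self.chols(params)
        except np.linalg.LinAlgError:
            return 1e12
        stacked = {}
        for sig, r in resid_groups:
            stacked.setdefault(sig, []).append(r)
        nll = 0.0
        for sig, rs in stacked.items():
            L = Ls[sig]
            Z = solve_triangular(L, np.column_stack(rs), lower=True)
            n_i = L.shape[0]
            nll += float(len(rs) * np.log(np.diag(L)).sum() + 0.5 * (Z * Z).sum()
                         + 0.5 * len(rs) * n_i * np.log(2 * np.pi))
        return nll


# ---------------------------------------------------------------- fitting


@dataclass
class GammFit:
    spec: GammSpec
    method: str
    coef: dict                  # name -> estimate (fixed + null-space columns)
    se: dict
    smooth_edf: float
    edf_total: float
    lam: float
    tau: float
    sigma: float
    ar: np.ndarray
    ma: np.ndarray
    loglik: float
    aic: float
    converged: bool
    n_iter: int
    design: Design
    beta: np.ndarray
    cov_beta: np.ndarray
    fitted: np.ndarray
    residuals: np.ndarray

    def summary_table(self) -> pd.DataFrame:
        """Coefficient table (Estimate, SE, z, p) for the linear terms,
        plus one row for the smoother with its effective degrees of freedom."""
        from scipy.stats import norm, f as fdist
        rows = []
        for name in self.coef:
            if name.startswith("s."):
                continue
            est, se = self.coef[name], self.se[name]
            z = est / se if se > 0 else np.nan
            rows.append({"term": name, "estimate": est, "se": se,
                         "p": 2 * norm.sf(abs(z))})
        f_stat, p_smooth = self._smooth_test()
        rows.append({"term": "s(lat,lon)", "estimate": np.nan, "se": np.nan,
                     "edf": self.smooth_edf, "F": f_stat, "p": p_smooth})
        return pd.DataFrame(rows)

    def _smooth_test(self):
        from scipy.stats import f as fdist
        idx = np.flatnonzero([n.startswith(("s(", "s.")) for n in self.design.col_names])
        b = self.beta[idx]
        Vb = self.cov_beta[np.ix_(idx, idx)]
        try:
            chi2 = float(b @ np.linalg.solve(Vb, b))
        except np.linalg.LinAlgError:
            return np.nan, np.nan
        df = max(self.smooth_edf + 2.0, 1.0)
        fstat = chi2 / df
        n = len(self.design.y)
        return fstat, float(fdist.sf(fstat, df, max(n - self.edf_total, 1)))


def _pls_path(Xw, yw, pen_mask, lam):
    A = Xw.T @ Xw
    b = Xw.T @ yw
    P = np.diag(pen_mask.astype(float))
    try:
        cho = cho_factor(A + lam * P)
    except np.linalg.LinAlgError:
        # near-singular unpenalized block (e.g. collinear covariates);
        # stabilize with a tiny ridge relative to the column scales
        eps = 1e-8 * max(np.trace(A) / A.shape[0], 1.0)
        cho = cho_factor(A + lam * P + eps * np.eye(A.shape[0]))
    beta = cho_solve(cho, b)
    H = cho_solve(cho, A)            # (A+lam P)^-1 A ; trace = total EDF
    edf_total = float(np.trace(H))
    edf_smooth = float(np.trace(H[np.ix_(pen_mask, pen_mask)]))
    rss = float(yw @ yw - 2 * beta @ b + beta @ A @ beta)
    return beta, edf_total, edf_smooth, rss, cho


def _choose_lambda(Xw, yw, pen_mask, gamma=1.4):
    n = len(yw)

    def gcv(loglam):
        beta, edf, _, rss, _ = _pls_path(Xw, yw, pen_mask, float(np.exp(loglam)))
        denom = max(n - gamma * edf, 1e-3)
        return n * rss / denom**2

    grid = np.linspace(-8, 12, 9)
    vals = [gcv(g) for g in grid]
    i = int(np.argmin(vals))
    lo, hi = grid[max(0, i - 1)], grid[min(len(grid) - 1, i + 1)]
    res = minimize_scalar(gcv, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-3})
    return float(np.exp(res.x))


def fit(series: pd.DataFrame, spec: GammSpec, max_iter=50, tol=1e-4,
        warm_var=None) -> GammFit:
    """Fit the persistence model; deterministic given the data.

    Alternates penalized GLS for the mean (GCV-chosen smoothing) with ML
    for the variance parameters until the marginal AIC stabilizes.  With
    ``spec.method == "REML"`` the variance parameters maximize the
    penalized restricted likelihood instead.  ``warm_var`` optionally
    seeds the variance parameters (used by backward elimination).
    """
    des = build_design(series, spec)
    p, q = spec.arma
    n = len(des.y)
    vm = _VarModel(des, p, q, spec.random_intercept)
    groups = []
    for (aid, pieces), sig in zip(des.runs, vm.signatures):
        idx = np.concatenate(pieces)
        groups.append((sig, idx))

    sd0 = float(np.std(des.y)) or 1.0
    params = warm_var if warm_var is not None else vm.pack(
        0.3 * sd0, sd0, np.zeros(p), np.zeros(q))
    prev_aic = np.inf
    lam = 1.0
    converged = False
    nvar = (1 if spec.random_intercept else 0) + 1 + p + q
    for it in range(max_iter):
        Ls = vm.chols(params)
        Xw = np.empty_like(des.X)
        yw = np.empty_like(des.y)
        for (sig, idx) in groups:
            L = Ls[sig]
            Xw[idx] = solve_triangular(L, des.X[idx], lower=True)
            yw[idx] = solve_triangular(L, des.y[idx], lower=True)
        lam = _choose_lambda(Xw, yw, des.pen_mask)
        beta, edf_total, edf_smooth, _, cho = _pls_path(Xw, yw, des.pen_mask, lam)
        resid = des.y - des.X @ beta
        rgroups = [(sig, resid[idx]) for sig, idx in groups]

        def obj(pp):
            val = vm.negloglik(pp, rgroups)
            if spec.method == "REML" and val < 1e11:
                val += _reml_adjustment(des, pp, vm, lam)
            return val

        res = minimize(obj, params, method="Nelder-Mead",
                       options={"maxiter": 120 * len(params), "xatol": 1e-5,
                                "fatol": 1e-7})
        params = res.x
        ll = -vm.negloglik(params, rgroups)
        aic = -2 * ll + 2 * (edf_total + nvar)
        if abs(aic - prev_aic) < tol:
            converged = True
            prev_aic = aic
            break
        prev_aic = aic

    # final mean-update pass so beta, lambda and the variance parameters are
    # mutually consistent (the loop breaks right after a variance update)
    Ls = vm.chols(params)
    Xw = np.empty_like(des.X)
    yw = np.empty_like(des.y)
    for (sig, idx) in groups:
        L = Ls[sig]
        Xw[idx] = solve_triangular(L, des.X[idx], lower=True)
        yw[idx] = solve_triangular(L, des.y[idx], lower=True)
    lam = _choose_lambda(Xw, yw, des.pen_mask)
    beta, edf_total, edf_smooth, _, cho = _pls_path(Xw, yw, des.pen_mask, lam)
    resid = des.y - des.X @ beta
    rgroups = [(sig, resid[idx]) for sig, idx in groups]
    ll = -vm.negloglik(params, rgroups)
    prev_aic = -2 * ll + 2 * (edf_total + nvar)

    tau, sigma, ar, ma = vm.unpack(params)
    cov_beta = cho_solve(cho, np.eye(des.X.shape[1]))
    coef = dict(zip(des.col_names, beta))
    se = dict(zip(des.col_names, np.sqrt(np.maximum(np.diag(cov_beta), 0))))
    fitted = des.X @ beta
    return GammFit(spec=spec, method=spec.method, coef=coef, se=se,
                   smooth_edf=edf_smooth, edf_total=edf_total, lam=lam,
                   tau=tau, sigma=sigma, ar=ar, ma=ma, loglik=ll, aic=prev_aic,
                   converged=converged, n_iter=it + 1, design=des, beta=beta,
                   cov_beta=cov_beta, fitted=fitted, residuals=des.y - fitted)


def _reml_adjustment(des, params, vm, lam):
    """Penalized-REML correction: 0.5 log|Xw' Xw + lam P| at the current
    variance parameters (drops constant terms)."""
    try:
        Ls = vm.chols(params)
    except np.linalg.LinAlgError:
        return 1e12
    Xw = np.empty_like(des.X)
    off = 0
    for (aid, pieces), sig in zip(des.runs, vm.signatures):
        idx = np.concatenate(pieces)
        Xw[idx] = solve_triangular(Ls[sig], des.X[idx], lower=True)
    A = Xw.T @ Xw + lam * np.diag(des.pen_mask.astype(float))
    sign, logdet = np.linalg.slogdet(A)
    return 0.5 * logdet if sign > 0 else 1e12


def select_arma(resid_series, max_order=4):
    """Choose ARMA orders for pooled per-animal residual series.

    The candidate grid is seeded by the last lag at which the pooled
    ACF (for q) and PACF (for p) leave the 95% band +-1.96/sqrt(N); the
    winner minimizes the pooled-likelihood AIC.  Series shorter than 5
    are ignored; if all are too short, (0, 0) is returned with a note.
    Deterministic given the input.
    """
    series = [np.asarray(s, float) for s in resid_series if len(s) >= 5]
    if not series or sum(len(s) for s in series) < 20:
        return (0, 0), pd.DataFrame([{"p": 0, "q": 0, "aic": np.nan,
                                      "note": "series too short"}])
    N = sum(len(s) for s in series)
    band = 1.96 / np.sqrt(N)
    maxlag = max(1, min(10, min(len(s) for s in series) // 2 - 1))
    acfs = np.mean([_acf(s, nlags=maxlag, fft=False)[1:] for s in series], axis=0)
    pacfs = np.mean([_pacf(s, nlags=maxlag, method="ywm")[1:] for s in series], axis=0)
    q0 = int(np.max(np.flatnonzero(np.abs(acfs) > band) + 1)) if (np.abs(acfs) > band).any() else 0
    p0 = int(np.max(np.flatnonzero(np.abs(pacfs) > band) + 1)) if (np.abs(pacfs) > band).any() else 0
    p0, q0 = min(p0, max_order), min(q0, max_order)

    rows = []
    best = None
    for p in range(p0 + 1):
        for q in range(q0 + 1):
            ll = _pooled_arma_ml(series, p, q)
            k = p + q + 1
            aic = -2 * ll + 2 * k
            rows.append({"p": p, "q": q, "loglik": ll, "aic": aic})
            if best is None or aic < best[0] - 1e-9:
                best = (aic, p, q)
    table = pd.DataFrame(rows)
    return (best[1], best[2]), table


def _pooled_arma_ml(series, p, q):
    """Maximized pooled Gaussian log-likelihood of a shared ARMA(p, q).

    Series of equal length share one Cholesky factor per evaluation.
    """
    sd = float(np.sqrt(np.mean([np.var(s) for s in series]))) or 1.0
    by_len = {}
    for s in series:
        by_len.setdefault(len(s), []).append(s)
    stacks = {n: np.column_stack(ss) for n, ss in by_len.items()}

    def nll(params):
        sigma = float(np.exp(np.clip(params[0], -12, 12)))
        i = 1
        ar = _constrain(params[i:i + p]) if p else np.empty(0)
        i += p
        ma = -_constrain(params[i:i + q]) if q else np.empty(0)
        total = 0.0
        try:
            for n, S in stacks.items():
                L = np.linalg.cholesky(_arma_cov(n, ar, ma, sigma**2))
                Z = solve_triangular(L, S, lower=True)
                k = S.shape[1]
                total += float(k * np.log(np.diag(L)).sum() + 0.5 * (Z * Z).sum()
                               + 0.5 * k * n * np.log(2 * np.pi))
        except np.linalg.LinAlgError:
            return 1e12
        return total

    x0 = np.r_[np.log(sd), np.zeros(p + q)]
    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 200 * max(1, p + q), "xatol": 1e-5, "fatol": 1e-7})
    return -float(res.fun)


def backward_eliminate(series: pd.DataFrame, spec: GammSpec, aic_tolerance=0.0):
    """AIC backward elimination of fixed effects under ML; REML refit at the end.

    Repeatedly drops the candidate whose removal most lowers the AIC
    until no drop improves it; the smoother and the random intercept
    are never dropped.  With the default strict rule the AIC of the
    selected model never exceeds the full model's.  A positive
    ``aic_tolerance`` switches to the parsimony convention (a removal
    that raises AIC by less than the tolerance still proceeds; 2 is the
    classic "indistinguishable within two AIC units" band), which trades
    a small risk of dropping weak true effects for fewer spuriously
    retained covariates.  AIC ties within 1e-6 are broken by dropping
    the covariate that appears later in the declared candidate order.
    Returns (final_fit, trace) where trace records the AIC path.
    """
    order = [c for c in spec.fixed_effects]
    current = list(order)
    ml_spec = GammSpec(fixed_effects=tuple(current), k=spec.k,
                       random_intercept=spec.random_intercept, arma=spec.arma,
                       method="ML")
    best = fit(series, ml_spec)
    warm_params = _pack_warm(best)
    trace = [{"step": 0, "dropped": None, "kept": tuple(current), "aic": best.aic}]
    step = 0
    while current:
        candidates = []
        for c in current:
            reduced = tuple(x for x in current if x != c)
            rspec = GammSpec(fixed_effects=reduced, k=spec.k,
                             random_intercept=spec.random_intercept,
                             arma=spec.arma, method="ML")
            f = fit(series, rspec, warm_var=warm_params)
            candidates.append((f.aic, order.index(c), c, f))
        # lowest AIC wins; tie -> drop the later covariate in declared order
        best_aic = min(a for a, _, _, _ in candidates)
        tied = [t for t in candidates if t[0] <= best_aic + 1e-6]
        tied.sort(key=lambda t: -t[1])
        aic_c, _, cname, fit_c = tied[0]
        if aic_c < best.aic + aic_tolerance:
            step += 1
            current.remove(cname)
            best = fit_c
            warm_params = _pack_warm(best)
            trace.append({"step": step, "dropped": cname, "kept": tuple(current),
                          "aic": best.aic})
        else:
            break
    final_spec = GammSpec(fixed_effects=tuple(current), k=spec.k,
                          random_intercept=spec.random_intercept, arma=spec.arma,
                          method="REML")
    final = fit(series, final_spec, warm_var=warm_params)
    return final, pd.DataFrame(trace)


def _pack_warm(f: GammFit):
    vm = _VarModel(f.design, *f.spec.arma, f.spec.random_intercept)
    return vm.pack(f.tau, f.sigma, f.ar, f.ma)


def predict(fitres: GammFit, new: pd.DataFrame, se=True):
    """Population-level predictions (random effect excluded) with SEs.

    ``new`` needs lat, lon and the retained covariates.  Rows outside
    the fitted covariate ranges are still predicted but flagged in the
    returned extrapolation mask.
    """
    des = fitres.design
    spec = fitres.spec
    blocks = [np.ones((len(new), 1))]
    for name in des.col_names[1:]:
        if name.startswith(("s(", "s.")):
            break
        if name.startswith("period["):
            lev = name[len("period["):-1]
            blocks.append((new["period"].astype(str) == lev).to_numpy(float)[:, None])
        else:
            blocks.append(new[name].to_numpy(dtype=float)[:, None])
    B = des.basis.design(new["lat"].to_numpy(dtype=float), new["lon"].to_numpy(dtype=float))
    X = np.column_stack(blocks + [B])
    mu = X @ fitres.beta
    out = {"mean": mu}
    if se:
        var = np.einsum("ij,jk,ik->i", X, fitres.cov_beta, X)
        out["se"] = np.sqrt(np.maximum(var, 0))
    tr_lat = (des.basis.center[0] - 3 * des.basis.scale[0],
              des.basis.center[0] + 3 * des.basis.scale[0])
    extrap = ((new["lat"].to_numpy(float) < tr_lat[0]) | (new["lat"].to_numpy(float) > tr_lat[1]))
    out["extrapolated"] = extrap
    return pd.DataFrame(out, index=new.index)


def prediction_grid(fitres: GammFit, n=25, covariate_values=None):
    """Evaluate the fitted surface on a lat/lon grid (for contour export)."""
    des = fitres.design
    la = des.basis.center[0] + des.basis.scale[0] * np.linspace(-2, 2, n)
    lo = des.basis.center[1] + des.basis.scale[1] * np.linspace(-2, 2, n)
    LA, LO = np.meshgrid(la, lo, indexing="ij")
    new = pd.DataFrame({"lat": LA.ravel(), "lon": LO.ravel()})
    for name in des.col_names[1:]:
        if name.startswith(("s(", "s.")):
            break
        if name.startswith("period["):
            new["period"] = (covariate_values or {}).get("period", des.period_levels[-1])
        else:
            new[name] = (covariate_values or {}).get(name, 0.0)
    pr = predict(fitres, new, se=False)
    return new.assign(mean=pr["mean"].to_numpy())
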