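"""The eleven regression procedures compared in the estimator study.

Each estimator regresses a standardized outcome on a standardized predictor
and reports the slope with a two-tailed 95% interval and an excludes-zero
decision:

1.  ``naive``          — OLS, no controls
2.  ``latitude``       — OLS + capital latitude
3.  ``longitude``      — OLS + capital longitude
4.  ``continent_fe``   — OLS + continent fixed effects
5.  ``family_fe``      — OLS + language-family fixed effects
6.  ``radius_2000km``  — OLS + mean of the predictor within a 2000-km radius
7.  ``conley_latlon``  — OLS with Conley (spatial-HAC) SEs on geodesic distance
8.  ``conley_ancestry``— OLS with Conley SEs on ancestry-surrogate distance
9.  ``gp_latlon``      — regression with a Gaussian process over (lon, lat)
10. ``phylo_ranef``    — regression with nation random intercepts covarying
                         according to linguistic proximity
11. ``gp_phylo``       — both the Gaussian process and the linguistic
                         random intercepts

The original study fitted 9–11 in a Bayesian framework; here all variance
components are estimated by (profile) maximum likelihood and intervals are
Wald-type, preserving the 95%-interval decision rule.  Conley corrections
follow the max-SE cutoff-selection rule: models are fitted over a grid of
feasible distance cutoffs and the cutoff yielding the largest slope SE is
retained (coefficients are unchanged by construction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as spo
import statsmodels.api as sm
from scipy import stats

from galton.proximity import NationTable, ProximityMatrix, pairwise_geodesic_km
from galton.simulate import Dataset

__all__ = ["FitResult", "METHODS", "fit_method", "fit_ols", "radius_mean",
           "fit_conley", "fit_gp", "fit_phylo_ranef", "fit_gp_phylo"]

METHODS = ("naive", "latitude", "longitude", "continent_fe", "family_fe",
           "radius_2000km", "conley_latlon", "conley_ancestry", "gp_latlon",
           "phylo_ranef", "gp_phylo")

_OLS_CONTROLS = {"naive": "none", "latitude": "latitude",
                 "longitude": "longitude", "continent_fe": "continent_fe",
                 "family_fe": "family_fe", "radius_2000km": "radius_mean"}

_Z975 = stats.norm.ppf(0.975)


@dataclass
class FitResult:
    """Standardized slope with 95% interval and the excludes-zero decision."""

    method: str
    slope: float
    se: float
    ci_low: float
    ci_high: float
    excludes_zero: bool = field(init=False)
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("interval must bracket the slope")
        self.excludes_zero = not (self.ci_low <= 0.0 <= self.ci_high)


def _standardize(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, float)
    sd = v.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("variable is constant; cannot standardize")
    return (v - v.mean()) / sd


def _align_nations(dataset: Dataset, nations: NationTable) -> pd.DataFrame:
    df = nations.data.set_index("nation_id")
    missing = [i for i in dataset.ids if i not in df.index]
    if missing:
        raise KeyError(f"dataset ids absent from nation table: {missing[:5]}")
    return df.loc[dataset.ids]


# ---------------------------------------------------------------------------
# OLS family
# ---------------------------------------------------------------------------

def radius_mean(x: np.ndarray, nations: NationTable,
                radius_km: float = 2000.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-nation mean of ``x`` over *other* nations within ``radius_km``.

    Nations with an empty neighbourhood get the global mean of ``x``;
    the second return value flags them.
    """
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    x = np.asarray(x, float)
    D = pairwise_geodesic_km(nations.latlon)
    mask = (D <= radius_km) & ~np.eye(len(x), dtype=bool)
    counts = mask.sum(axis=1)
    out = np.where(counts > 0, (mask @ x) / np.maximum(counts, 1), x.mean())
    return out, counts == 0


def _design(dataset: Dataset, nations: NationTable | None,
            controls: str) -> tuple[np.ndarray, np.ndarray, dict]:
    y = _standardize(dataset.y)
    x = _standardize(dataset.x)
    cols = [np.ones_like(x), x]
    diag: dict = {}
    if controls != "none":
        if nations is None:
            raise ValueError(f"controls {controls!r} require a nation table")
        nd = _align_nations(dataset, nations)
        if controls == "latitude":
            cols.append(nd["capital_lat"].to_numpy(float))
        elif controls == "longitude":
            cols.append(nd["capital_lon"].to_numpy(float))
        elif controls in ("continent_fe", "family_fe"):
            col = "continent" if controls == "continent_fe" else "majority_family"
            levels = sorted(nd[col].unique())
            counts = nd[col].value_counts()
            single = counts[counts == 1].index.tolist()
            if single:
                warnings.warn(
                    f"{col} levels with a single member absorb their own "
                    f"observation: {single}", UserWarning, stacklevel=3)
            for lev in levels[1:]:  # first (alphabetical) level is reference
                cols.append((nd[col] == lev).to_numpy(float))
            diag["n_levels"] = len(levels)
        elif controls == "radius_mean":
            rm, empty = radius_mean(x, nations)
            cols.append(rm)
            diag["n_empty_neighbourhoods"] = int(empty.sum())
        else:
            raise ValueError(f"unknown control set: {controls!r}")
    X = np.column_stack(cols)
    return y, X, diag


def fit_ols(dataset: Dataset, controls: str = "none",
            nations: NationTable | None = None) -> FitResult:
    """OLS of standardized y on standardized x plus the named controls.

    ``controls`` is one of none / latitude / longitude / continent_fe /
    family_fe / radius_mean.  Fixed effects are dummy-coded with the first
    (alphabetical) level as reference.  The interval is from the t
    distribution.
    """
    y, X, diag = _design(dataset, nations, controls)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient (collinear controls)")
    res = sm.OLS(y, X).fit()
    ci = res.conf_int(alpha=0.05)
    method = {v: k for k, v in _OLS_CONTROLS.items()}[controls]
    diag.update(controls=controls, df_resid=float(res.df_resid))
    return FitResult(method, float(res.params[1]), float(res.bse[1]),
                     float(ci[1, 0]), float(ci[1, 1]), diagnostics=diag)


# ---------------------------------------------------------------------------
# Conley spatial-HAC standard errors
# ---------------------------------------------------------------------------

DEFAULT_CONLEY_CUTOFFS_KM = tuple(float(c) for c in range(500, 5001, 500))


def _conley_se(X: np.ndarray, e: np.ndarray, D: np.ndarray,
               cutoff: float) -> float | None:
    """Slope SE from the Bartlett-kernel spatial-HAC sandwich at one cutoff."""
    W = np.clip(1.0 - D / cutoff, 0.0, None)
    bread = np.linalg.inv(X.T @ X)
    meat = X.T @ ((W * np.outer(e, e)) @ X)
    V = bread @ meat @ bread
    v = V[1, 1]
    if v <= 0 or not np.isfinite(v):
        return None
    return float(np.sqrt(v))


def fit_conley(dataset: Dataset, nations: NationTable, coords: str = "latlon",
               cutoffs=None) -> FitResult:
    """OLS slope with Conley (spatial-HAC, Bartlett kernel) standard errors.

    ``coords`` selects the distance space: capital ``latlon`` (geodesic km)
    or ``ancestry`` surrogate coordinates (Euclidean; nations without
    ancestry coordinates are dropped).  Following the max-SE rule, the fit
    is repeated over the cutoff grid and the cutoff giving the largest slope
    SE is reported.  The point estimate is plain OLS: the correction changes
    only the standard error.
    """
    nd = _align_nations(dataset, nations)
    y, x = dataset.y, dataset.x
    if coords == "latlon":
        D = pairwise_geodesic_km(nd[["capital_lat", "capital_lon"]].to_numpy(float))
        keep = np.ones(len(y), bool)
        if cutoffs is None:
            cutoffs = DEFAULT_CONLEY_CUTOFFS_KM
    elif coords == "ancestry":
        xy = nd[["ancestry_x", "ancestry_y"]].to_numpy(float)
        keep = ~np.isnan(xy).any(axis=1)
        if keep.sum() < 4:
            raise ValueError("too few nations with ancestry coordinates")
        xy = xy[keep]
        diff = xy[:, None, :] - xy[None, :, :]
        D = np.sqrt((diff ** 2).sum(axis=-1))
        if cutoffs is None:
            off = D[~np.eye(len(D), dtype=bool)]
            cutoffs = np.quantile(off[off > 0], np.linspace(0.1, 1.0, 10))
    else:
        raise ValueError(f"unknown coordinate space: {coords!r}")
    y = _standardize(np.asarray(y, float)[keep])
    x = _standardize(np.asarray(x, float)[keep])
    X = np.column_stack([np.ones_like(x), x])
    ols = sm.OLS(y, X).fit()
    e = y - X @ ols.params
    best_se, best_cut = None, None
    for c in cutoffs:
        se = _conley_se(X, e, D, float(c))
        if se is not None and (best_se is None or se > best_se):
            best_se, best_cut = se, float(c)
    if best_se is None:
        raise ValueError("no cutoff produced a valid (positive) slope variance")
    slope = float(ols.params[1])
    method = "conley_latlon" if coords == "latlon" else "conley_ancestry"
    return FitResult(method, slope, best_se,
                     slope - _Z975 * best_se, slope + _Z975 * best_se,
                     diagnostics={"cutoff": best_cut, "n_used": int(keep.sum()),
                                  "coords": coords})


# ---------------------------------------------------------------------------
# variance-component estimators (profile maximum likelihood)
# ---------------------------------------------------------------------------

def _gls_concentrated(y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """Concentrated Gaussian log-likelihood for V = s^2 W with s^2 profiled.

    Returns (loglik, beta, scaled covariance of beta without s^2, s2_ml,
    cholesky of W).
    """
    n = len(y)
    c = np.linalg.cholesky(W)
    Xw = sla.solve_triangular(c, X, lower=True)
    yw = sla.solve_triangular(c, y, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    s2 = rss / n
    logdet = 2.0 * np.log(np.diag(c)).sum()
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, beta, np.linalg.inv(XtX), s2, rss


def _wald_result(method: str, y, X, W, diag: dict) -> FitResult:
    """GLS slope and normal-based interval at the chosen covariance W."""
    n, k = X.shape
    _, beta, XtXinv, _, rss = _gls_concentrated(y, X, W)
    s2 = rss / (n - k)
    se = float(np.sqrt(s2 * XtXinv[1, 1]))
    slope = float(beta[1])
    return FitResult(method, slope, se, slope - _Z975 * se,
                     slope + _Z975 * se, diagnostics=diag)


def _scaled_coords(nations_df: pd.DataFrame) -> np.ndarray:
    """(lon, lat) min–max scaled per axis to the unit square."""
    z = nations_df[["capital_lon", "capital_lat"]].to_numpy(float)
    lo, hi = z.min(axis=0), z.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (z - lo) / span


def _sqdist(coords: np.ndarray) -> np.ndarray:
    return ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)


def _rbf(d2: np.ndarray, length_scale: float) -> np.ndarray:
    return np.exp(-0.5 * d2 / length_scale ** 2)


def _grid_refine(objective, grid_points, tol=1e-8):
    """Coarse multi-start grid search refined by one local simplex run."""
    vals = [(objective(np.asarray(p, float)), tuple(p)) for p in grid_points]
    vals.sort(key=lambda t: t[0])
    best = None
    for _, p in vals[:2]:  # refine from the two best grid starts
        res = spo.minimize(objective, np.asarray(p, float), method="Nelder-Mead",
                           options={"xatol": 1e-6, "fatol": tol,
                                    "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("variance-component optimization failed to converge")
    return best


def fit_gp(dataset: Dataset, nations: NationTable) -> FitResult:
    """Regression with a Gaussian process over (longitude, latitude).

    y = β₀ + β₁x + f(coords) + e with an exponentiated-quadratic kernel on
    per-axis min–max-scaled coordinates.  The signal-to-noise ratio and
    length-scale maximize the (concentrated) marginal likelihood from
    multiple starts; β₁ and its SE come from GLS at the optimum.
    """
    nd = _align_nations(dataset, nations)
    n = len(dataset.ids)
    if n < 8:
        raise ValueError("too few nations to estimate GP hyperparameters")
    y = _standardize(dataset.y)
    x = _standardize(dataset.x)
    X = np.column_stack([np.ones(n), x])
    d2 = _sqdist(_scaled_coords(nd))
    In = np.eye(n)

    def nll(theta):
        log_a, log_ell = theta
        if abs(log_a) > 12 or not -6 < log_ell < 4:
            return 1e10
        W = np.exp(log_a) * _rbf(d2, np.exp(log_ell)) + In
        try:
            ll, *_ = _gls_concentrated(y, X, W)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll

    starts = [(la, le) for la in (-3.0, -1.5, 0.0, 1.5, 3.0)
              for le in (-3.0, -2.0, -1.0, 0.0, 1.0)]
    best = _grid_refine(nll, starts)
    log_a, log_ell = best.x
    a, ell = np.exp(log_a), np.exp(log_ell)
    W = a * _rbf(d2, ell) + In
    _, _, _, s2, _ = _gls_concentrated(y, X, W)
    diag = {"gp_amplitude_var": a * s2, "gp_length_scale": ell,
            "resid_var": s2, "loglik": -best.fun}
    return _wald_result("gp_latlon", y, X, W, diag)


def _eig_cache_key(L: ProximityMatrix):
    return id(L)


_EIG_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def _eig(L: ProximityMatrix) -> tuple[np.ndarray, np.ndarray]:
    key = _eig_cache_key(L)
    if key not in _EIG_CACHE:
        if len(_EIG_CACHE) > 16:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = np.linalg.eigh(L.values)
    return _EIG_CACHE[key]


def fit_phylo_ranef(dataset: Dataset, L: ProximityMatrix,
                    fix_h: float | None = None) -> FitResult:
    """Regression with nation random intercepts covarying as linguistic proximity.

    y = β₀ + β₁x + u + e with u ~ MVN(0, σ_u² L).  The variance fraction
    h = σ_u²/(σ_u²+σ_e²) is profiled over [0, 1) on a one-time
    eigendecomposition of L (grid search refined by bounded minimization);
    β₁ via GLS at the optimum, normal-based interval.  ``fix_h`` pins the
    variance fraction instead of estimating it.
    """
    if list(L.ids) != list(dataset.ids):
        raise ValueError("L ids misaligned with dataset ids")
    lam, Q = _eig(L)
    if lam.min() <= 0:
        raise ValueError("L must be positive definite; run as_correlation first")
    n = L.n
    y = Q.T @ _standardize(dataset.y)
    x = _standardize(dataset.x)
    X = Q.T @ np.column_stack([np.ones(n), x])
    identifiable = lam.max() - lam.min() > 1e-10

    def nll_h(h):
        v = h * lam + (1.0 - h)
        Xw = X / np.sqrt(v)[:, None]
        yw = y / np.sqrt(v)
        XtX = Xw.T @ Xw
        beta = np.linalg.solve(XtX, Xw.T @ yw)
        rss = float((yw - Xw @ beta) @ (yw - Xw @ beta))
        s2 = rss / n
        return 0.5 * (n * np.log(2.0 * np.pi * s2) + np.log(v).sum() + n)

    if fix_h is not None:
        if not 0.0 <= fix_h < 1.0:
            raise ValueError("fix_h must lie in [0, 1)")
        h = float(fix_h)
    elif identifiable:
        hs = np.linspace(0.0, 0.99, 34)
        vals = [nll_h(h) for h in hs]
        i = int(np.argmin(vals))
        lo = hs[max(i - 1, 0)]
        hi = min(hs[min(i + 1, len(hs) - 1)], 0.999)
        res = spo.minimize_scalar(nll_h, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-9})
        h = float(res.x) if res.fun <= vals[i] else float(hs[i])
    else:
        h = 0.0
    v = h * lam + (1.0 - h)
    Xw = X / np.sqrt(v)[:, None]
    yw = y / np.sqrt(v)
    XtXinv = np.linalg.inv(Xw.T @ Xw)
    beta = XtXinv @ (Xw.T @ yw)
    rss = float((yw - Xw @ beta) @ (yw - Xw @ beta))
    s2 = rss / (n - X.shape[1])
    se = float(np.sqrt(s2 * XtXinv[1, 1]))
    slope = float(beta[1])
    diag = {"h": h, "sigma_u2": h * s2, "resid_var": (1.0 - h) * s2,
            "identifiable": identifiable, "loglik": -nll_h(h)}
    return FitResult("phylo_ranef", slope, se, slope - _Z975 * se,
                     slope + _Z975 * se, diagnostics=diag)


def fit_gp_phylo(dataset: Dataset, nations: NationTable,
                 L: ProximityMatrix) -> FitResult:
    """Joint model: spatial Gaussian process plus linguistic random intercepts.

    V = σ² (a_g K_ℓ + a_u L + I); the three hyperparameters (log variance
    ratios and log length-scale) maximize the concentrated likelihood; GLS
    slope at the optimum.
    """
    if list(L.ids) != list(dataset.ids):
        raise ValueError("L ids misaligned with dataset ids")
    nd = _align_nations(dataset, nations)
    n = len(dataset.ids)
    if n < 8:
        raise ValueError("too few nations to estimate joint hyperparameters")
    y = _standardize(dataset.y)
    x = _standardize(dataset.x)
    X = np.column_stack([np.ones(n), x])
    d2 = _sqdist(_scaled_coords(nd))
    Lv = L.values
    In = np.eye(n)

    def nll(theta):
        log_ag, log_au, log_ell = theta
        if max(abs(log_ag), abs(log_au)) > 12 or not -6 < log_ell < 4:
            return 1e10
        W = (np.exp(log_ag) * _rbf(d2, np.exp(log_ell))
             + np.exp(log_au) * Lv + In)
        try:
            ll, *_ = _gls_concentrated(y, X, W)
        except np.linalg.LinAlgError:
            return 1e10
        return -ll

    starts = [(ag, au, le) for ag in (-2.0, 0.0, 2.0)
              for au in (-2.0, 0.0, 2.0) for le in (-2.5, -1.0, 0.0)]
    best = _grid_refine(nll, starts)
    log_ag, log_au, log_ell = best.x
    W = (np.exp(log_ag) * _rbf(d2, np.exp(log_ell))
         + np.exp(log_au) * Lv + In)
    _, _, _, s2, _ = _gls_concentrated(y, X, W)
    diag = {"gp_amplitude_var": np.exp(log_ag) * s2,
            "ling_var": np.exp(log_au) * s2, "resid_var": s2,
            "gp_length_scale": float(np.exp(log_ell)), "loglik": -best.fun}
    return _wald_result("gp_phylo", y, X, W, diag)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def fit_method(method: str, dataset: Dataset, world) -> FitResult:
    """Fit one of the eleven named estimators using a World for side data."""
    if method in _OLS_CONTROLS:
        return fit_ols(dataset, _OLS_CONTROLS[method], world.nations)
    if method == "conley_latlon":
        return fit_conley(dataset, world.nations, coords="latlon")
    if method == "conley_ancestry":
        return fit_conley(dataset, world.nations, coords="ancestry")
    if method == "gp_latlon":
        return fit_gp(dataset, world.nations)
    if method == "phylo_ranef":
        return fit_phylo_ranef(dataset, world.ling_C.reindex(dataset.ids))
    if method == "gp_phylo":
        return fit_gp_phylo(dataset, world.nations,
                            world.ling_C.reindex(dataset.ids))
    raise KeyError(f"unknown method {method!r}; choose from {METHODS}")
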