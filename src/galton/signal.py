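"""Geographic and cultural-phylogenetic signal via variance components.

For a nation-level trait observed once or repeatedly per nation, the mixed
model

    value_it = mu + g_i + l_i + u_i + e_it,
    g ~ MVN(0, sigma_g^2 G),  l ~ MVN(0, sigma_l^2 L),
    u ~ iid nation,           e ~ iid observation,

lets nation intercepts covary simultaneously according to a geographic
correlation matrix G and a linguistic correlation matrix L.  The iid nation
term u is dropped when every nation is observed once (it would be
confounded with e).  Components are estimated by restricted maximum
likelihood with multi-start optimization on log-variances.

The *signal* proportions are shares of nation-level variance:

* longitudinal / individual data:  signal_geo = sigma_g^2 / (sigma_g^2 +
  sigma_l^2 + sigma_u^2) — the observation-level residual is within-nation
  variance and is excluded from the denominator;
* cross-sectional data: the residual IS nation-level, so it is included:
  signal_geo = sigma_g^2 / (sigma_g^2 + sigma_l^2 + sigma_e^2).

Intervals come from the profile likelihood of each component (nuisance
components re-optimized), mapped to the proportion scale.  Evidence that a
component differs from zero uses a likelihood-ratio test against the
boundary mixture 0.5*chi2_0 + 0.5*chi2_1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize as spo
from scipy import stats

from galton.proximity import ProximityMatrix

__all__ = ["TraitTable", "SignalEstimate", "fit_signal_model", "lrt_component"]

_LOG_FLOOR = -18.0  # log-variance treated as zero


@dataclass
class TraitTable:
    """Rows of (nation_id, value) with an optional repeat index column ``period``."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data.copy()
        if "nation_id" not in df.columns or "value" not in df.columns:
            raise ValueError("TraitTable needs nation_id and value columns")
        df["nation_id"] = df["nation_id"].astype(str)
        df = df.dropna(subset=["value"]).reset_index(drop=True)  # listwise
        if df["nation_id"].nunique() < 2:
            raise ValueError("need non-missing values for at least 2 nations")
        self.data = df

    @classmethod
    def from_csv(cls, path) -> "TraitTable":
        return cls(pd.read_csv(path, float_precision="round_trip"))

    @property
    def longitudinal(self) -> bool:
        return bool(self.data["nation_id"].duplicated().any())


@dataclass
class SignalEstimate:
    """Variance components and the geographic/linguistic signal proportions."""

    var_geo: float
    var_ling: float
    var_nation_iid: float
    var_resid: float
    signal_geo: float
    signal_ling: float
    loglik: float
    n_obs: int
    n_nations: int
    longitudinal: bool
    ci: dict = field(default_factory=dict)
    _fitter: object = field(default=None, repr=False, compare=False)

    @property
    def components(self) -> dict:
        return {"geo": self.var_geo, "ling": self.var_ling,
                "nation_iid": self.var_nation_iid, "resid": self.var_resid}


class _SignalFitter:
    """REML machinery for the two-matrix variance-component model."""

    def __init__(self, trait: TraitTable, G: ProximityMatrix, L: ProximityMatrix):
        df = trait.data
        ids = sorted(df["nation_id"].unique())
        for M, name in ((G, "G"), (L, "L")):
            missing = set(ids) - set(M.ids)
            if missing:
                raise KeyError(f"nations absent from {name}: {sorted(missing)[:5]}")
        self.ids = ids
        self.G = G.reindex(ids).values
        self.L = L.reindex(ids).values
        n = len(ids)
        if np.linalg.norm(self.G - self.L) / n < 1e-8:
            raise ValueError("G and L coincide; components are not identifiable")
        y = df["value"].to_numpy(float)
        if y.std() == 0:
            raise ValueError("trait is constant")
        self.longitudinal = bool(df["nation_id"].duplicated().any())
        geo_iid = np.allclose(self.G, np.eye(n), atol=1e-10)
        ling_iid = np.allclose(self.L, np.eye(n), atol=1e-10)
        if geo_iid and ling_iid:
            raise ValueError("G = L = I: components not separable from iid terms")
        pos = {nid: i for i, nid in enumerate(ids)}
        self.map_idx = df["nation_id"].map(pos).to_numpy()
        self.scale = y.std(ddof=1)
        self.center = y.mean()
        # components are estimated on the standardized trait and reported back
        # on the trait scale; rounding far below statistical precision makes
        # the fit exactly invariant to rescaling the input
        self.y = np.round((y - self.center) / self.scale, 12)
        self.n_obs = len(y)
        self.n_nations = n
        # component names active in this design
        self.names = (["geo", "ling", "nation_iid", "resid"]
                      if self.longitudinal else ["geo", "ling", "resid"])

    def _cov(self, var: dict) -> np.ndarray:
        A = var["geo"] * self.G + var["ling"] * self.L
        if self.longitudinal:
            A = A + var["nation_iid"] * np.eye(self.n_nations)
            V = A[np.ix_(self.map_idx, self.map_idx)]
            V = V + var["resid"] * np.eye(self.n_obs)
        else:
            V = A[np.ix_(self.map_idx, self.map_idx)] + var["resid"] * np.eye(self.n_obs)
        return V

    def reml(self, var: dict) -> float:
        V = self._cov(var)
        n = self.n_obs
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return -np.inf
        from scipy.linalg import solve_triangular
        X = np.ones((n, 1))
        Xw = solve_triangular(c, X, lower=True)
        yw = solve_triangular(c, self.y, lower=True)
        xtx = float((Xw[:, 0] * Xw[:, 0]).sum())
        mu = float(Xw[:, 0] @ yw) / xtx
        resid = yw - Xw[:, 0] * mu
        quad = float(resid @ resid)
        logdet = 2.0 * np.log(np.diag(c)).sum()
        return -0.5 * ((n - 1) * np.log(2 * np.pi) + logdet + np.log(xtx) + quad)

    def fit(self, fix: dict | None = None, n_starts: int = 5):
        """Maximize REML over log-variances, with optional components fixed.

        Returns (variance dict on the standardized scale, loglik).
        """
        fix = dict(fix or {})
        free = [nm for nm in self.names if nm not in fix]
        if not free:
            var = {nm: fix.get(nm, 0.0) for nm in self.names}
            return var, self.reml(var)

        def unpack(theta):
            var = {nm: float(v) for nm, v in fix.items()}
            for nm, t in zip(free, theta):
                var[nm] = float(np.exp(np.clip(t, _LOG_FLOOR, 12.0)))
            return var

        def nll(theta):
            ll = self.reml(unpack(theta))
            return 1e10 if not np.isfinite(ll) else -ll

        k = len(free)
        rng = np.random.default_rng(12345)
        base = np.log(max(1.0 / max(len(self.names), 1), 1e-3))
        starts = [np.full(k, base)]
        for _ in range(n_starts - 1):
            starts.append(rng.uniform(-5.0, 1.0, size=k))
        best = None
        for x0 in starts:
            res = spo.minimize(nll, x0, method="Nelder-Mead",
                               options={"xatol": 1e-7, "fatol": 1e-9,
                                        "maxiter": 4000})
            if best is None or res.fun < best.fun:
                best = res
        var = unpack(best.x)
        # snap effectively-zero components to exact zero
        for nm in free:
            if var[nm] < 1.5e-8:
                var[nm] = 0.0
        return var, self.reml(var)

    # -- intervals ----------------------------------------------------------

    def profile_ci(self, component: str, var_hat: dict, ll_hat: float,
                   level: float = 0.95) -> tuple[float, float]:
        """Profile-likelihood interval for one variance component."""
        crit = stats.chi2.ppf(level, df=1) / 2.0  # 1.92 at 95%
        t_hat = var_hat[component]

        def deficit(t):
            _, ll = self.fit(fix={component: t}, n_starts=2)
            return ll_hat - ll

        # lower bound
        if deficit(0.0) <= crit:
            lo = 0.0
        else:
            lo = _bisect_monotone(deficit, 0.0, max(t_hat, 1e-8), crit,
                                  decreasing=True)
        # upper bound: expand until past the threshold
        hi = max(t_hat, 1e-6)
        for _ in range(40):
            hi *= 2.0
            if deficit(hi) > crit:
                break
        else:
            return lo, np.inf
        hi = _bisect_monotone(deficit, max(t_hat, 1e-8), hi, crit,
                              decreasing=False)
        return lo, hi


def _bisect_monotone(f, a, b, target, decreasing, tol=1e-3, maxit=40):
    """Find t with f(t) = target for f monotone on [a, b]."""
    for _ in range(maxit):
        m = 0.5 * (a + b)
        v = f(m)
        above = v > target
        if (above and decreasing) or (not above and not decreasing):
            a = m
        else:
            b = m
        if b - a < tol * max(b, 1.0):
            break
    return 0.5 * (a + b)


def _proportions(var: dict, longitudinal: bool) -> tuple[float, float]:
    denom = var["geo"] + var["ling"]
    denom += var.get("nation_iid", 0.0) if longitudinal else var["resid"]
    if denom <= 0:
        return 0.0, 0.0
    return var["geo"] / denom, var["ling"] / denom


def fit_signal_model(trait: TraitTable, G: ProximityMatrix, L: ProximityMatrix,
                     n_starts: int = 5, ci: bool = True) -> SignalEstimate:
    """REML fit of the joint geographic + linguistic signal model.

    ``G`` and ``L`` must be positive-definite unit-diagonal correlation
    matrices covering every nation in the trait table.  Set ``ci=False`` to
    skip the (more expensive) profile-likelihood intervals.
    """
    fitter = _SignalFitter(trait, G, L)
    var_std, ll = fitter.fit(n_starts=n_starts)
    s2 = fitter.scale ** 2
    var = {nm: v * s2 for nm, v in var_std.items()}
    var.setdefault("nation_iid", 0.0)
    sg, sl = _proportions(var, fitter.longitudinal)
    cis: dict = {}
    if ci:
        for comp in ("geo", "ling"):
            lo, hi = fitter.profile_ci(comp, var_std, ll)
            cis[f"var_{comp}"] = (lo * s2, hi * s2)
            # proportion endpoints with nuisances at their profile optima
            pr = []
            for t in (lo, hi):
                v_t, _ = fitter.fit(fix={comp: t}, n_starts=2)
                v_t = {nm: vv * s2 for nm, vv in v_t.items()}
                v_t.setdefault("nation_iid", 0.0)
                p = _proportions(v_t, fitter.longitudinal)
                pr.append(p[0] if comp == "geo" else p[1])
            cis[f"signal_{comp}"] = (min(pr), max(pr))
    est = SignalEstimate(
        var_geo=var["geo"], var_ling=var["ling"],
        var_nation_iid=var["nation_iid"], var_resid=var["resid"],
        signal_geo=sg, signal_ling=sl,
        loglik=ll, n_obs=fitter.n_obs, n_nations=fitter.n_nations,
        longitudinal=fitter.longitudinal, ci=cis)
    est._fitter = fitter
    return est


def lrt_component(full: SignalEstimate, component: str) -> tuple[float, float]:
    """Boundary-mixture likelihood-ratio test that a signal component is zero.

    Refits the model with the named component (``geo`` or ``ling``) fixed at
    0 and compares restricted log-likelihoods.  Under the null the statistic
    follows the 0.5*chi2_0 + 0.5*chi2_1 mixture (the variance sits on the
    boundary of its parameter space).
    """
    if component not in ("geo", "ling"):
        raise ValueError("component must be 'geo' or 'ling'")
    fitter = full._fitter
    if fitter is None:
        raise ValueError("estimate does not carry refit state")
    _, ll0 = fitter.fit(fix={component: 0.0}, n_starts=4)
    ll1 = full.loglik
    stat = 2.0 * (ll1 - ll0)
    if stat < -1e-4:
        _, ll1b = fitter.fit(n_starts=10)
        stat = 2.0 * (max(ll1, ll1b) - ll0)
        if stat < -1e-4:
            raise RuntimeError("full-model likelihood below reduced model; "
                               "optimization failed")
    stat = max(stat, 0.0)
    p = 1.0 if stat == 0.0 else 0.5 * float(stats.chi2.sf(stat, df=1))
    return stat, p
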