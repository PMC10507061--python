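import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from galton import (Dataset, ProximityMatrix, as_correlation, fit_conley,
                    fit_gp, fit_gp_phylo, fit_method, fit_ols,
                    fit_phylo_ranef, radius_mean, simulate_dataset)
from galton.estimators import METHODS, _standardize
from galton.proximity import NationTable


def make_dataset(y, x, ids=None):
    n = len(y)
    ids = ids or [f"N{i:03d}" for i in range(n)]
    return Dataset(ids, np.asarray(y, float), np.asarray(x, float),
                   np.zeros(n), np.zeros(n))


def world_dataset(world, lam=0.0, rho=0.0, r=0.0, seed=0, sigma="geographic"):
    return simulate_dataset(world.sigma(sigma), lam, rho, r, seed=seed)


def _implied_offdiag(fit, world):
    """Mean |off-diagonal| of the fitted between-nation correlation structure."""
    from galton.estimators import _rbf, _scaled_coords, _sqdist
    d = fit.diagnostics
    total = d["resid_var"] + d.get("gp_amplitude_var", 0.0) + d.get("ling_var", 0.0)
    n = world.nations.n
    S = np.zeros((n, n))
    if "gp_amplitude_var" in d:
        K = _rbf(_sqdist(_scaled_coords(world.nations.data)),
                 d["gp_length_scale"])
        S = S + d["gp_amplitude_var"] * K
    if "ling_var" in d:
        S = S + d["ling_var"] * world.ling_C.values
    off = ~np.eye(n, dtype=bool)
    return np.abs(S[off]).mean() / total


class TestOLS:
    def test_perfect_relationship(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        fit = fit_ols(make_dataset(x.copy(), x))
        assert fit.slope == pytest.approx(1.0, abs=1e-10)
        assert fit.excludes_zero

    def test_continent_fe_equals_demeaned_ols(self, small_world):
        """Frisch–Waugh: fixed effects = OLS on within-group demeaned data."""
        ds = world_dataset(small_world, 0.5, 0.5, 0.3, seed=1)
        fit = fit_ols(ds, "continent_fe", small_world.nations)
        cont = small_world.nations.data["continent"].to_numpy()
        y, x = _standardize(ds.y), _standardize(ds.x)
        yd = y - pd.Series(y).groupby(cont).transform("mean").to_numpy()
        xd = x - pd.Series(x).groupby(cont).transform("mean").to_numpy()
        beta = float(xd @ yd / (xd @ xd))
        assert fit.slope == pytest.approx(beta, abs=1e-8)

    def test_collinear_design_rejected(self, small_world):
        cont = small_world.nations.data["continent"].astype("category")
        x = cont.cat.codes.to_numpy(float)  # x constant within continents
        rng = np.random.default_rng(1)
        ds = make_dataset(rng.normal(size=len(x)), x, ids=small_world.ids)
        with pytest.raises(ValueError, match="rank"):
            fit_ols(ds, "continent_fe", small_world.nations)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_ols(make_dataset(np.arange(5.0), np.ones(5)))

    def test_interval_brackets_slope_for_all_controls(self, small_world):
        ds = world_dataset(small_world, 0.2, 0.2, 0.0, seed=2)
        for controls in ("none", "latitude", "longitude", "continent_fe",
                         "radius_mean"):
            fit = fit_ols(ds, controls, small_world.nations)
            assert fit.ci_low <= fit.slope <= fit.ci_high


class TestRadiusMean:
    @staticmethod
    def nations(coords):
        return NationTable(pd.DataFrame({
            "nation_id": [f"N{i}" for i in range(len(coords))],
            "capital_lat": [c[0] for c in coords],
            "capital_lon": [c[1] for c in coords],
            "continent": "Africa", "majority_family": "Uralic"}))

    def test_single_neighbour(self):
        # 0-10 degrees on the equator ~ 1112 km < 2000; 0-100 degrees >> 2000
        nt = self.nations([(0, 0), (0, 10), (0, 100)])
        x = np.array([1.0, 5.0, 9.0])
        rm, empty = radius_mean(x, nt)
        assert rm[0] == pytest.approx(5.0)
        assert rm[1] == pytest.approx(1.0)

    def test_isolated_nation_falls_back_to_global_mean(self):
        nt = self.nations([(0, 0), (0, 10), (0, 100)])
        x = np.array([1.0, 5.0, 9.0])
        rm, empty = radius_mean(x, nt)
        assert empty.tolist() == [False, False, True]
        assert rm[2] == pytest.approx(x.mean())

    def test_dense_neighbourhood_is_leave_one_out_mean(self):
        nt = self.nations([(0, 0), (0, 3), (0, 6), (1, 3)])
        x = np.array([2.0, 4.0, 6.0, 8.0])
        rm, empty = radius_mean(x, nt)
        assert not empty.any()
        for i in range(4):
            loo = np.delete(x, i).mean()
            assert rm[i] == pytest.approx(loo)

    def test_nonpositive_radius_rejected(self):
        nt = self.nations([(0, 0), (0, 10), (0, 20)])
        with pytest.raises(ValueError):
            radius_mean(np.ones(3), nt, radius_km=0)


class TestConley:
    def test_subminimum_cutoff_equals_hc0(self, small_world):
        """With no pair inside the cutoff only the diagonal survives: HC0."""
        ds = world_dataset(small_world, 0.5, 0.5, 0.0, seed=3)
        fit = fit_conley(ds, small_world.nations, cutoffs=[1e-6])
        y, x = _standardize(ds.y), _standardize(ds.x)
        X = sm.add_constant(x)
        hc0 = sm.OLS(y, X).fit().HC0_se[1]
        assert fit.se == pytest.approx(hc0, abs=1e-8)

    def test_point_estimate_equals_ols_for_any_cutoff(self, small_world):
        ds = world_dataset(small_world, 0.5, 0.5, 0.0, seed=4)
        ols = fit_ols(ds)
        for cutoffs in ([100.0], [3000.0], [100.0, 3000.0, 8000.0]):
            fit = fit_conley(ds, small_world.nations, cutoffs=cutoffs)
            assert fit.slope == pytest.approx(ols.slope, abs=1e-12)

    def test_duplicated_rows_inflate_se(self, small_world):
        """Perfectly dependent duplicates at shared coordinates raise the SE."""
        rng = np.random.default_rng(5)
        n = small_world.nations.n
        half = rng.normal(size=(2, n // 2))
        y = np.concatenate([half[0], half[0]])
        x = np.concatenate([half[1], half[1]])
        nd = small_world.nations.data.copy()
        nd.loc[n // 2:, "capital_lat"] = nd.loc[:n // 2 - 1, "capital_lat"].to_numpy()
        nd.loc[n // 2:, "capital_lon"] = nd.loc[:n // 2 - 1, "capital_lon"].to_numpy()
        nations = NationTable(nd)
        ds = make_dataset(y, x, ids=nations.ids)
        # cutoff covers only the duplicate pairs (distance 0)
        fit = fit_conley(ds, nations, cutoffs=[1.0])
        iid_se = fit_ols(ds).se
        assert fit.se > iid_se

    def test_max_se_cutoff_retained(self, small_world):
        ds = world_dataset(small_world, 0.8, 0.8, 0.0, seed=6)
        cutoffs = [500.0, 2000.0, 5000.0]
        ses = [fit_conley(ds, small_world.nations, cutoffs=[c]).se
               for c in cutoffs]
        fit = fit_conley(ds, small_world.nations, cutoffs=cutoffs)
        assert fit.se == pytest.approx(max(ses))
        assert fit.diagnostics["cutoff"] == cutoffs[int(np.argmax(ses))]

    def test_ancestry_drops_uncovered_nations(self, small_world):
        ds = world_dataset(small_world, 0.5, 0.5, 0.0, seed=7)
        fit = fit_conley(ds, small_world.nations, coords="ancestry")
        mask, _ = small_world.nations.ancestry_coords()
        assert fit.diagnostics["n_used"] == int(mask.sum())
        assert fit.diagnostics["n_used"] < small_world.nations.n


class TestGP:
    def test_reduces_to_ols_without_spatial_signal(self, small_world):
        """With no spatial signal the fitted GP is effectively absent.

        The collapse can happen two ways: amplitude near zero, or a
        length-scale so short the kernel is diagonal.  Either way the
        implied between-nation covariance vanishes and the GLS slope is OLS.
        """
        ds = world_dataset(small_world, 0.0, 0.0, 0.3, seed=8)
        gp = fit_gp(ds, small_world.nations)
        ols = fit_ols(ds)
        assert _implied_offdiag(gp, small_world) < 0.15
        assert gp.slope == pytest.approx(ols.slope, abs=0.03)

    def test_too_few_nations_rejected(self, small_world):
        ds = make_dataset([1.0, 2.0, 0.5], [0.2, -1.0, 0.3],
                          ids=small_world.ids[:3])
        with pytest.raises(ValueError, match="few"):
            fit_gp(ds, small_world.nations)

    def test_smooth_spatial_outcome_not_attributed_to_noise_predictor(
            self, small_world):
        """y = smooth surface + noise, x pure noise: no false association."""
        nd = small_world.nations.data
        rng = np.random.default_rng(9)
        hits = 0
        for rep in range(10):
            y = (np.sin(np.radians(nd["capital_lat"])) * 2
                 + np.cos(np.radians(nd["capital_lon"]))
                 + 0.1 * rng.normal(size=len(nd)))
            x = rng.normal(size=len(nd))
            ds = make_dataset(y.to_numpy(), x, ids=small_world.ids)
            hits += fit_gp(ds, small_world.nations).excludes_zero
        assert hits <= 1


class TestPhyloRanef:
    def test_identity_matrix_equals_ols(self, small_world):
        ds = world_dataset(small_world, 0.3, 0.3, 0.0, seed=10)
        L = ProximityMatrix(ds.ids, np.eye(len(ds.ids)))
        fit = fit_phylo_ranef(ds, L)
        ols = fit_ols(ds)
        assert fit.slope == pytest.approx(ols.slope, abs=1e-8)
        assert not fit.diagnostics["identifiable"]

    def test_fixed_h_matches_closed_form_gls(self, small_world):
        """β̂ at pinned h equals (X'V⁻¹X)⁻¹X'V⁻¹y with V = hL + (1-h)I."""
        L = small_world.ling_C
        for seed, h in [(11, 0.3), (12, 0.7), (13, 0.05)]:
            ds = world_dataset(small_world, 0.5, 0.5, 0.2, seed=seed,
                               sigma="linguistic")
            fit = fit_phylo_ranef(ds, L, fix_h=h)
            y, x = _standardize(ds.y), _standardize(ds.x)
            X = np.column_stack([np.ones_like(x), x])
            V = h * L.values + (1 - h) * np.eye(L.n)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            assert fit.slope == pytest.approx(float(beta[1]), abs=1e-8)

    def test_variance_fraction_recovery(self, mid_world):
        """True h = λ = 0.5 on Σ = L is recovered within ±0.15 (median)."""
        L = mid_world.ling_C
        hs = []
        for rep in range(50):
            ds = simulate_dataset(L, 0.5, 0.0, 0.0, seed=1000 + rep)
            hs.append(fit_phylo_ranef(ds, L).diagnostics["h"])
        assert abs(np.median(hs) - 0.5) < 0.15

    def test_misaligned_ids_rejected(self, small_world):
        ds = world_dataset(small_world, 0.2, 0.2, 0.0, seed=14)
        L = small_world.ling_C.reindex(list(reversed(ds.ids)))
        with pytest.raises(ValueError, match="misaligned"):
            fit_phylo_ranef(ds, L)


class TestGPPhylo:
    def test_reduces_to_ols_without_structure(self, small_world):
        ds = world_dataset(small_world, 0.0, 0.0, 0.3, seed=15)
        fit = fit_gp_phylo(ds, small_world.nations, small_world.ling_C)
        ols = fit_ols(ds)
        assert _implied_offdiag(fit, small_world) < 0.15
        assert fit.slope == pytest.approx(ols.slope, abs=0.08)

    def test_misaligned_ids_rejected(self, small_world):
        ds = world_dataset(small_world, 0.2, 0.2, 0.0, seed=16)
        L = small_world.ling_C.reindex(list(reversed(ds.ids)))
        with pytest.raises(ValueError, match="misaligned"):
            fit_gp_phylo(ds, small_world.nations, L)


class TestInvariances:
    @pytest.mark.parametrize("method", ["naive", "continent_fe",
                                        "conley_latlon", "phylo_ranef"])
    def test_sign_flips_transform_slope_keep_decision(self, small_world, method):
        ds = world_dataset(small_world, 0.5, 0.5, 0.3, seed=17)
        both = Dataset(ds.ids, -ds.y, -ds.x, -ds.alpha_y, -ds.alpha_x)
        xonly = Dataset(ds.ids, ds.y, -ds.x, ds.alpha_y, -ds.alpha_x)
        f1 = fit_method(method, ds, small_world)
        f2 = fit_method(method, both, small_world)
        f3 = fit_method(method, xonly, small_world)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-6)
        assert f3.slope == pytest.approx(-f1.slope, abs=1e-6)
        assert f2.excludes_zero == f1.excludes_zero == f3.excludes_zero

    def test_excludes_zero_consistent_with_interval(self, small_world):
        for m in METHODS:
            fit = fit_method(m, world_dataset(small_world, 0.5, 0.5, 0.0,
                                              seed=18), small_world)
            assert fit.excludes_zero == (not fit.ci_low <= 0.0 <= fit.ci_high)

    def test_unknown_method_rejected(self, small_world):
        with pytest.raises(KeyError):
            fit_method("bayes", world_dataset(small_world), small_world)
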