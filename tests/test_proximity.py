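import numpy as np
import pandas as pd
import pytest

from galton import (
    LanguageTaxonomy,
    NationTable,
    ProximityMatrix,
    SpeakerTable,
    as_correlation,
    geodesic_distance_km,
    geographic_proximity_matrix,
    language_pair_proximity,
    linguistic_proximity_matrix,
)
from galton.proximity import EARTH_RADIUS_KM

from conftest import (brute_force_proximities, random_tuple_tree,
                      tuple_tree_newick)


def nation_table(coords, **extra):
    n = len(coords)
    df = pd.DataFrame({
        "nation_id": [f"N{i}" for i in range(n)],
        "capital_lat": [c[0] for c in coords],
        "capital_lon": [c[1] for c in coords],
        "continent": extra.get("continent", ["Africa"] * n),
        "majority_family": extra.get("family", ["Indo-European"] * n),
    })
    return NationTable(df)


class TestGeodesic:
    def test_identical_points_zero(self):
        assert geodesic_distance_km(10, 20, 10, 20) == 0.0

    @pytest.mark.parametrize("p2, fraction", [((0, 180), 0.5), ((0, 90), 0.25)])
    def test_great_circle_fractions(self, p2, fraction):
        expected = fraction * 2 * np.pi * EARTH_RADIUS_KM
        assert geodesic_distance_km(0, 0, *p2) == pytest.approx(expected, abs=1e-6)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.uniform([-90, -180], [90, 180])
            b = rng.uniform([-90, -180], [90, 180])
            d1 = geodesic_distance_km(a[0], a[1], b[0], b[1])
            d2 = geodesic_distance_km(b[0], b[1], a[0], a[1])
            assert d1 == pytest.approx(d2) and d1 >= 0

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            geodesic_distance_km(95, 0, 0, 0)
        with pytest.raises(ValueError):
            geodesic_distance_km(0, 200, 0, 0)


class TestGeographicProximity:
    def test_collinear_distances_map_to_extremes(self):
        # equator points at lon 0, 10, 20: distances d, d, 2d
        P = geographic_proximity_matrix(nation_table([(0, 0), (0, 10), (0, 20)]))
        assert P.values[0, 1] == pytest.approx(1.0)
        assert P.values[1, 2] == pytest.approx(1.0)
        assert P.values[0, 2] == pytest.approx(0.0)

    def test_unit_diagonal_and_range(self):
        rng = np.random.default_rng(1)
        coords = [(la, lo) for la, lo in
                  zip(rng.uniform(-60, 60, 8), rng.uniform(-170, 170, 8))]
        P = geographic_proximity_matrix(nation_table(coords))
        assert np.all(np.diag(P.values) == 1.0)
        off = P.values[~np.eye(8, dtype=bool)]
        assert off.min() == pytest.approx(0.0, abs=1e-12)
        assert off.max() == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_capitals_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            geographic_proximity_matrix(
                nation_table([(0, 0), (0, 0), (10, 10)]))

    def test_equidistant_configuration_rejected(self):
        # three equator points 120 degrees apart are mutually equidistant
        with pytest.raises(ValueError, match="degenerate"):
            geographic_proximity_matrix(
                nation_table([(0, 0), (0, 120), (0, -120)]))

    def test_longitude_shift_invariance(self):
        """A global longitude shift preserves all distances, hence the matrix."""
        rng = np.random.default_rng(2)
        lats = rng.uniform(-60, 60, 6)
        lons = rng.uniform(-170, 170, 6)
        P1 = geographic_proximity_matrix(nation_table(list(zip(lats, lons))))
        P2 = geographic_proximity_matrix(
            nation_table(list(zip(lats, (lons + 37.0)))))
        np.testing.assert_allclose(P1.values, P2.values, atol=1e-9)


class TestLanguagePairProximity:
    def test_toy_tree_values(self, toy_tree):
        assert language_pair_proximity(toy_tree, "L1", "L1") == 1.0
        assert language_pair_proximity(toy_tree, "L1", "L2") == pytest.approx(2 / 3)
        assert language_pair_proximity(toy_tree, "L1", "L3") == pytest.approx(1 / 3)
        assert language_pair_proximity(toy_tree, "L1", "L4") == 0.0

    def test_unknown_tip_rejected(self, toy_tree):
        with pytest.raises(KeyError):
            language_pair_proximity(toy_tree, "L1", "nope")

    def test_matches_brute_force_on_random_trees(self):
        """Exact agreement with an independent root-path oracle, 200 trees."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            tup = random_tuple_tree(rng, int(rng.integers(3, 21)))
            tips, oracle = brute_force_proximities(tup)
            tree = LanguageTaxonomy.from_newick(tuple_tree_newick(tup))
            S = tree.proximity_matrix(tips)
            for i, a in enumerate(tips):
                for j, b in enumerate(tips):
                    assert S[i, j] == pytest.approx(oracle[(a, b)], abs=0), \
                        f"pair {a},{b} in {tuple_tree_newick(tup)}"

    def test_single_pair_matches_matrix(self, toy_tree):
        S = toy_tree.proximity_matrix(["L1", "L3", "L4"])
        assert S[0, 1] == language_pair_proximity(toy_tree, "L1", "L3")
        assert S[0, 2] == language_pair_proximity(toy_tree, "L1", "L4")


def speakers(rows):
    return SpeakerTable(pd.DataFrame(rows, columns=["nation_id", "language_id",
                                                    "share"]))


class TestLinguisticProximity:
    def test_monolingual_same_language_gives_one(self, toy_tree):
        W = linguistic_proximity_matrix(
            toy_tree, speakers([("a", "L1", 1.0), ("b", "L1", 1.0)]))
        assert W.values[0, 1] == pytest.approx(1.0)

    def test_monolingual_root_mrca_gives_zero(self, toy_tree):
        W = linguistic_proximity_matrix(
            toy_tree, speakers([("a", "L1", 1.0), ("b", "L4", 1.0)]))
        assert W.values[0, 1] == pytest.approx(0.0)

    def test_speaker_weighted_mixture(self, toy_tree):
        # w = 0.5*s(L1,L2) + 0.5*s(L3,L2) = 0.5*(2/3) + 0.5*(1/3) = 0.5
        W = linguistic_proximity_matrix(
            toy_tree, speakers([("l", "L1", 0.5), ("l", "L3", 0.5),
                                ("m", "L2", 1.0)]))
        i, j = W.ids.index("l"), W.ids.index("m")
        assert W.values[i, j] == pytest.approx(0.5)

    def test_raw_diagonal_recorded_but_unit_enforced(self, toy_tree):
        W = linguistic_proximity_matrix(
            toy_tree, speakers([("l", "L1", 0.5), ("l", "L4", 0.5),
                                ("m", "L2", 1.0)]))
        i = W.ids.index("l")
        assert np.all(np.diag(W.values) == 1.0)
        assert W.raw_diagonal[i] < 1.0  # multilingual nation, s(L1,L4)=0 terms

    def test_nation_below_threshold_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="zz"):
            linguistic_proximity_matrix(
                toy_tree, speakers([("zz", "L1", 0.0005), ("m", "L2", 1.0)]),
                threshold=0.001)

    def test_row_order_invariance(self, toy_tree):
        rows = [("a", "L1", 0.6), ("a", "L3", 0.4), ("b", "L2", 1.0),
                ("c", "L4", 1.0)]
        W1 = linguistic_proximity_matrix(toy_tree, speakers(rows))
        W2 = linguistic_proximity_matrix(toy_tree, speakers(rows[::-1]))
        np.testing.assert_allclose(W1.values, W2.values, atol=1e-15)
        assert W1.ids == W2.ids

    def test_tip_rotation_invariance(self):
        """Swapping child order in the Newick leaves every proximity unchanged."""
        t1 = LanguageTaxonomy.from_newick("(((L1,L2)a1,L3)A,(L4)B);")
        t2 = LanguageTaxonomy.from_newick("((L4)B,((L2,L1)a1,L3)A);")
        rows = [("a", "L1", 0.7), ("a", "L2", 0.3), ("b", "L3", 1.0),
                ("c", "L4", 1.0)]
        W1 = linguistic_proximity_matrix(t1, speakers(rows))
        W2 = linguistic_proximity_matrix(t2, speakers(rows))
        np.testing.assert_allclose(W1.values, W2.values, atol=1e-15)

    def test_share_validation(self):
        with pytest.raises(ValueError):
            speakers([("a", "L1", 1.2)])
        with pytest.raises(ValueError):
            speakers([("a", "L1", 0.8), ("a", "L2", 0.5)])


class TestAsCorrelation:
    def test_identity_passthrough(self):
        P = ProximityMatrix(["a", "b", "c"], np.eye(3))
        C = as_correlation(P)
        np.testing.assert_allclose(C.values, np.eye(3))
        assert not C.pd_repaired

    def test_already_pd_unchanged(self):
        P = ProximityMatrix(["a", "b"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        C = as_correlation(P)
        np.testing.assert_allclose(C.values, P.values, atol=1e-12)
        assert not C.pd_repaired

    def test_rank_deficient_repaired(self):
        V = np.full((3, 3), 1.0)  # rank one: eigenvalues {3, 0, 0}
        P = ProximityMatrix(["a", "b", "c"], V)
        with pytest.warns(UserWarning):
            C = as_correlation(P, eig_floor=1e-6, max_entry_change=1e-9)
        w = np.linalg.eigvalsh(C.values)
        assert w.min() >= 1e-6
        assert np.all(np.diag(C.values) == 1.0)
        assert C.pd_repaired
        assert C.frobenius_delta > 0

    def test_strict_mode_escalates(self):
        V = np.array([[1.0, 1.0, 0.0], [1.0, 1.0, 1.0], [0.0, 1.0, 1.0]])
        P = ProximityMatrix(["a", "b", "c"], V)
        with pytest.raises(ValueError, match="repair"):
            as_correlation(P, strict=True)


class TestContainers:
    def test_longitude_normalized_on_read(self):
        nt = nation_table([(0, 190.0), (0, -180.0), (10, 20)])
        lons = nt.data["capital_lon"].to_numpy()
        assert lons[0] == pytest.approx(-170.0)
        assert lons[1] == 180.0

    def test_duplicate_ids_rejected(self):
        df = nation_table([(0, 0), (1, 1), (2, 2)]).data.copy()
        df.loc[1, "nation_id"] = df.loc[0, "nation_id"]
        with pytest.raises(ValueError, match="duplicate"):
            NationTable(df)

    def test_matrix_csv_roundtrip(self, tmp_path):
        P = ProximityMatrix(["a", "b", "c"],
                            np.array([[1, .2, .3], [.2, 1, .4], [.3, .4, 1.]]))
        P.to_csv(tmp_path / "m.csv")
        Q = ProximityMatrix.from_csv(tmp_path / "m.csv")
        assert Q.ids == P.ids
        np.testing.assert_allclose(Q.values, P.values)

    def test_reindex_subsets_and_reorders(self):
        P = ProximityMatrix(["a", "b", "c"],
                            np.array([[1, .2, .3], [.2, 1, .4], [.3, .4, 1.]]))
        Q = P.reindex(["c", "a"])
        assert Q.ids == ["c", "a"]
        assert Q.values[0, 1] == pytest.approx(0.3)
        with pytest.raises(KeyError):
            P.reindex(["a", "zz"])
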