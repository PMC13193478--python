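"""Occurrence geometry, thinning, extraction, VIF and scaling."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from mimodiv import env as envm
from mimodiv.simulate import simulate_occurrences


def ray_cast_inside(poly_coords, x, y):
    """Independent even-odd ray-casting point-in-polygon check."""
    inside = False
    n = len(poly_coords)
    for i in range(n):
        x1, y1 = poly_coords[i]
        x2, y2 = poly_coords[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestFilterNative:
    def test_inside_point_retained(self):
        occ = envm.OccurrenceSet("sp", np.array([[0.5, 0.5]]))
        poly = Polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert len(envm.filter_native(occ, poly)) == 1

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            envm.OccurrenceSet("sp", np.array([[200.0, 0.0]]))

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            envm.OccurrenceSet("sp", np.array([[1.0, 2.0], [1.0, 2.0]]))

    def test_missing_polygon_warns_or_drops(self):
        occ = envm.OccurrenceSet("sp", np.array([[0.5, 0.5]]))
        with pytest.warns(UserWarning, match="no native polygon"):
            kept = envm.filter_native(occ, None)
        assert len(kept) == 1
        assert len(envm.filter_native(occ, None, on_missing="drop")) == 0

    def test_agrees_with_ray_casting_oracle(self, rng):
        import warnings

        warnings.filterwarnings("ignore", message=".*non-native points")
        hits = 0
        for _ in range(20):
            pts = rng.uniform(-5, 5, size=(8, 2))
            poly = envm.convex_hull(pts)
            coords = list(poly.exterior.coords)[:-1]
            probes = rng.uniform(-6, 6, size=(50, 2))
            # skip probes essentially on the boundary (oracle conventions differ)
            for x, y in probes:
                d = poly.exterior.distance(Point(x, y))
                if d < 1e-9:
                    continue
                expected = ray_cast_inside(coords, x, y)
                occ = envm.OccurrenceSet("t", np.array([[x, y]]) / 100.0 * 100)
                got = envm.filter_native(occ, poly, on_missing="drop")
                assert (len(got) == 1) == expected
                hits += 1
        assert hits >= 900


class TestConvexHull:
    def test_square_with_center(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5]])
        hull = envm.convex_hull(pts)
        assert hull.area == pytest.approx(1.0)
        assert len(hull.exterior.coords) - 1 == 4

    def test_contains_all_points_vertices_subset(self, rng):
        pts = rng.uniform(0, 10, size=(100, 2))
        hull = envm.convex_hull(pts)
        assert all(hull.covers(Point(*p)) for p in pts)
        vset = {tuple(np.round(c, 9)) for c in hull.exterior.coords}
        pset = {tuple(np.round(p, 9)) for p in pts}
        assert vset <= pset

    def test_area_matches_monotone_chain_oracle(self, rng):
        def oracle_hull_area(points):
            pts = sorted(map(tuple, points))

            def half(ps):
                out = []
                for p in ps:
                    while len(out) >= 2 and (
                        (out[-1][0] - out[-2][0]) * (p[1] - out[-2][1])
                        - (out[-1][1] - out[-2][1]) * (p[0] - out[-2][0])
                    ) <= 0:
                        out.pop()
                    out.append(p)
                return out

            lower, upper = half(pts), half(reversed(pts))
            ring = lower[:-1] + upper[:-1]
            area = 0.0
            for i in range(len(ring)):
                x1, y1 = ring[i]
                x2, y2 = ring[(i + 1) % len(ring)]
                area += x1 * y2 - x2 * y1
            return abs(area) / 2

        for _ in range(5):
            pts = rng.uniform(-3, 3, size=(10, 2))
            assert envm.convex_hull(pts).area == pytest.approx(oracle_hull_area(pts))

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            envm.convex_hull(np.empty((0, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            envm.convex_hull(np.array([[0, 0], [1, 1]]))
        buffered = envm.convex_hull(np.array([[0, 0], [1, 1]]), degenerate_buffer=0.1)
        assert buffered.area > 0


class TestRandomPoints:
    def test_exact_cell_count_returns_all(self):
        poly = Polygon([(0, 0), (5, 0), (5, 4), (0, 4)])
        pts = envm.random_points_in_polygon(poly, n=20, grid_res=1.0, seed=1)
        assert len(pts) == 20
        assert all(poly.covers(Point(*p)) for p in pts)
        assert len({tuple(p) for p in pts}) == 20  # without replacement

    def test_seed_reproducibility(self):
        poly = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        a = envm.random_points_in_polygon(poly, n=10, grid_res=0.5, seed=3)
        b = envm.random_points_in_polygon(poly, n=10, grid_res=0.5, seed=3)
        c = envm.random_points_in_polygon(poly, n=10, grid_res=0.5, seed=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_uniform_over_cells(self):
        poly = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])  # 100 cells at res 1
        counts: dict = {}
        for s in range(2000):
            for p in envm.random_points_in_polygon(poly, n=5, grid_res=1.0, seed=s):
                counts[tuple(p)] = counts.get(tuple(p), 0) + 1
        freq = np.array(list(counts.values()))
        assert len(counts) == 100
        n_draws, p_cell = 2000 * 5, 1 / 100
        sd = np.sqrt(n_draws * p_cell * (1 - p_cell))
        assert np.all(np.abs(freq - n_draws * p_cell) < 4.5 * sd)

    def test_fewer_cells_than_requested_warns(self):
        poly = Polygon([(0, 0), (3, 0), (3, 1), (0, 1)])
        with pytest.warns(UserWarning, match="grid cells"):
            pts = envm.random_points_in_polygon(poly, n=20, grid_res=1.0, seed=0)
        assert len(pts) == 3


class TestThinning:
    def test_pair_below_threshold(self):
        # ~1.0 km apart at the equator (1 deg ~ 111.2 km)
        pts = np.array([[0.0, 0.0], [0.009, 0.0]])
        assert len(envm.thin_points(pts, min_km=1.5, seed=0)) == 1

    def test_pair_above_threshold(self):
        pts = np.array([[0.0, 0.0], [0.018, 0.0]])  # ~2.0 km
        assert len(envm.thin_points(pts, min_km=1.5, seed=0)) == 2

    def test_constraint_and_idempotence(self, rng):
        for _ in range(5):
            pts = rng.normal([0, 0], 0.01, size=(40, 2))
            pts = np.unique(pts, axis=0)
            out = envm.thin_points(pts, min_km=1.5, seed=2)
            D = envm.haversine_km(out)
            np.fill_diagonal(D, np.inf)
            assert D.min() >= 1.5
            again = envm.thin_points(out, min_km=1.5, seed=99)
            assert len(again) == len(out)

    def test_greedy_close_to_exact_mis(self, rng):
        import networkx as nx

        for _ in range(10):
            pts = np.unique(rng.normal([10, -5], 0.02, size=(12, 2)), axis=0)
            D = envm.haversine_km(pts)
            np.fill_diagonal(D, np.inf)
            G = nx.Graph((np.argwhere(np.triu(D < 1.5))).tolist())
            G.add_nodes_from(range(len(pts)))
            # exact maximum independent set = complement-graph max clique
            mis = max(
                (len(c) for c in nx.find_cliques(nx.complement(G))), default=len(pts)
            )
            kept = len(envm.thin_points(pts, min_km=1.5, seed=1))
            assert kept >= 0.8 * mis


class TestSpeciesEnvSummary:
    def test_study_cohort_routing(self):
        """226 species (182 well-sampled, 44 sparse) all get one table row;
        sparse species are routed through random points, never mixed."""
        occ, grid, polys = simulate_occurrences(
            n_species=226, n_sparse=44, points_per_species=8, seed=5
        )
        tab = envm.species_env_summary(occ, grid, polys, seed=5)
        assert len(tab) == 226
        assert (tab["provenance"] == "random").sum() == 44
        assert (tab["provenance"] == "observed").sum() == 182
        assert tab.attrs["excluded"] == []

    def test_constant_layer_gives_constant_value(self):
        occ, grid, polys = simulate_occurrences(n_species=8, n_sparse=2, seed=3)
        grid.layers["flat"] = np.full(grid.shape, 7.5)
        tab = envm.species_env_summary(occ, grid, polys, seed=3)
        np.testing.assert_allclose(tab["flat"], 7.5)

    def test_gradient_matches_point_mean(self):
        """On a noise-free linear gradient the species value equals the
        gradient evaluated at the (thinned) point centroid."""
        occ, grid, polys = simulate_occurrences(
            n_species=6, n_sparse=0, noise=0.0, seed=9
        )
        tab = envm.species_env_summary(occ, grid, polys, thin_km=0.0001, seed=9)
        for _, row in tab.iterrows():
            o = next(o for o in occ if o.species == row["species"])
            lon, lat = o.points[:, 0].mean(), o.points[:, 1].mean()
            expected = 200 + 25 * (lon + 80) + 2 * (lat + 30)  # GSP gradient
            assert row["GSP"] == pytest.approx(expected, rel=0.01)


class TestVif:
    def test_orthogonal_columns(self):
        n = 40
        X = np.zeros((n, 3))
        X[:, 0] = np.tile([1, -1], n // 2)
        X[:, 1] = np.tile([1, 1, -1, -1], n // 4)
        X[:, 2] = np.tile([1, -1, -1, 1], n // 4)
        v = envm.vif(X)
        np.testing.assert_allclose(v, 1.0, atol=1e-10)

    def test_high_correlation_closed_form(self, rng):
        """r = 0.93 between two predictors gives VIF = 1/(1-r^2) ~ 7.37."""
        n = 100_000
        z = rng.standard_normal(n)
        r = 0.93
        x1 = z
        x2 = r * z + np.sqrt(1 - r**2) * rng.standard_normal(n)
        v = envm.vif(np.column_stack([x1, x2]))
        np.testing.assert_allclose(v, 1 / (1 - 0.93**2), rtol=0.02)
        assert v.attrs["flagged"] == ["x0", "x1"]  # both above threshold 5

    def test_three_column_regression_oracle(self, rng):
        X = rng.standard_normal((60, 3))
        X[:, 2] += 0.7 * X[:, 0]
        v = envm.vif(X)
        for j in range(3):
            y = X[:, j]
            Z = np.column_stack([np.ones(60), np.delete(X, j, axis=1)])
            beta = np.linalg.solve(Z.T @ Z, Z.T @ y)
            r2 = 1 - np.sum((y - Z @ beta) ** 2) / np.sum((y - y.mean()) ** 2)
            assert v.iloc[j] == pytest.approx(1 / (1 - r2), rel=1e-8)
        assert (v >= 1).all()

    def test_perfect_collinearity_infinite(self, rng):
        x = rng.standard_normal(30)
        v = envm.vif(np.column_stack([x, 2 * x, rng.standard_normal(30)]))
        assert np.isinf(v.iloc[0]) and np.isinf(v.iloc[1])


class TestScale2SD:
    def test_scaled_moments_and_round_trip(self, rng):
        df = pd.DataFrame({"a": rng.normal(3, 2, 200), "b": rng.uniform(0, 1, 200)})
        scaled, consts = envm.scale_2sd(df)
        for c in ("a", "b"):
            assert scaled[c].mean() == pytest.approx(0.0, abs=1e-12)
            assert scaled[c].std(ddof=1) == pytest.approx(0.5, abs=1e-12)
        back = envm.unscale_2sd(scaled, consts)
        np.testing.assert_allclose(back["a"], df["a"], atol=1e-12)

    def test_zero_variance_rejected(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0]})
        with pytest.raises(ValueError, match="zero-variance column 'a'"):
            envm.scale_2sd(df)
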