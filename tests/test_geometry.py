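"""Surface clusters, areas, map assignment and topography statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import Delaunay

from numprf.geometry import (
    BinningSpec,
    Cluster,
    CoordinatePolynomialModel,
    MapAssignmentConfig,
    SurfaceMesh,
    assign_maps,
    bin_preferred_numerosity,
    cluster_surface_area,
    connected_clusters,
    coordinate_polynomial_model,
    geometry_correlations,
    numerosity_range,
    read_mesh,
    write_mesh_ascii,
)
from numprf.simulate import planar_mesh


def _random_mesh(rng, n=400):
    pts = rng.uniform(0, 10, size=(n, 2))
    tri = Delaunay(pts)
    coords = np.column_stack([pts, np.zeros(n)])
    return SurfaceMesh(coords, tri.simplices)


class TestConnectedClusters:
    def test_two_disjoint_patches(self):
        mesh = planar_mesh(10, 10)
        mask = np.zeros(100, dtype=bool)
        mask[[0, 1, 10]] = True  # corner patch
        mask[[88, 89, 99]] = True  # opposite corner patch
        clusters = connected_clusters(mesh, mask)
        assert len(clusters) == 2

    def test_isolated_vertex_is_singleton(self):
        mesh = planar_mesh(5, 5)
        mask = np.zeros(25, dtype=bool)
        mask[12] = True
        clusters = connected_clusters(mesh, mask)
        assert len(clusters) == 1
        assert clusters[0].size == 1

    def test_empty_mask(self):
        assert connected_clusters(planar_mesh(3, 3), np.zeros(9, bool)) == []

    def test_mask_length_validated(self):
        with pytest.raises(ValueError, match="length"):
            connected_clusters(planar_mesh(3, 3), np.zeros(5, bool))

    def test_matches_breadth_first_search_oracle(self, rng):
        """Connected components agree with a networkx BFS partition on
        random Delaunay meshes."""
        import networkx as nx

        for _ in range(10):
            mesh = _random_mesh(rng)
            mask = rng.uniform(size=mesh.n_vertices) < 0.3
            clusters = connected_clusters(mesh, mask)
            g = nx.Graph()
            g.add_nodes_from(np.flatnonzero(mask))
            for a, b in mesh.edges():
                if mask[a] and mask[b]:
                    g.add_edge(a, b)
            expected = {frozenset(c) for c in nx.connected_components(g)}
            got = {frozenset(c.vertex_ids.tolist()) for c in clusters}
            assert got == expected

    def test_clusters_partition_selected_set(self, rng):
        mesh = _random_mesh(rng, 300)
        mask = rng.uniform(size=mesh.n_vertices) < 0.4
        clusters = connected_clusters(mesh, mask)
        all_ids = np.concatenate([c.vertex_ids for c in clusters]) \
            if clusters else np.array([], dtype=int)
        assert len(all_ids) == len(set(all_ids.tolist()))  # disjoint
        assert set(all_ids.tolist()) == set(np.flatnonzero(mask).tolist())


class TestClusterArea:
    def _unit_square_mesh(self):
        coords = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]], float)
        tris = np.array([[0, 1, 2], [1, 3, 2]])
        return SurfaceMesh(coords, tris)

    def test_unit_right_triangle(self):
        mesh = self._unit_square_mesh()
        cl = Cluster(vertex_ids=np.array([0, 1, 2]))
        assert cluster_surface_area(mesh, cl) == pytest.approx(0.5)

    def test_triangle_with_excluded_vertex_contributes_nothing(self):
        mesh = self._unit_square_mesh()
        cl = Cluster(vertex_ids=np.array([0, 1]))
        assert cluster_surface_area(mesh, cl) == 0.0

    def test_unit_square(self):
        mesh = self._unit_square_mesh()
        cl = Cluster(vertex_ids=np.array([0, 1, 2, 3]))
        assert cluster_surface_area(mesh, cl) == pytest.approx(1.0)

    def test_split_halves_lose_boundary_triangles(self):
        """Interior-triangle areas of two halves sum to at most the whole."""
        mesh = planar_mesh(8, 8)
        whole = Cluster(vertex_ids=np.arange(64))
        left = Cluster(vertex_ids=np.arange(32))
        right = Cluster(vertex_ids=np.arange(32, 64))
        a_whole = cluster_surface_area(mesh, whole)
        a_parts = (cluster_surface_area(mesh, left)
                   + cluster_surface_area(mesh, right))
        assert a_parts <= a_whole + 1e-12
        assert a_parts < a_whole  # boundary strip genuinely drops out


class TestAssignMaps:
    def _cfg(self, **kw):
        centers = {"NPO": (0.0, 0.0, 0.0), "NTO": (100.0, 0.0, 0.0)}
        base = dict(a_min_mm2=50.0, d_max_mm=25.0, reference_centers=centers)
        base.update(kw)
        return MapAssignmentConfig(**base)

    def _cluster_at(self, mesh, ids):
        cl = Cluster(vertex_ids=np.asarray(ids))
        cl.area_mm2 = cluster_surface_area(mesh, cl)
        cl.center = mesh.coordinates[ids].mean(axis=0)
        return cl

    def test_small_cluster_unassigned(self):
        mesh = planar_mesh(4, 4)  # whole mesh area 9 mm^2 < A_min
        cl = self._cluster_at(mesh, np.arange(16))
        out = assign_maps([cl], self._cfg(), mesh)
        assert out[0].map_label == "unassigned"

    def test_cluster_within_reach_labelled(self):
        mesh = planar_mesh(12, 12)  # 121 mm^2, vertex (0,0) at the NPO center
        cl = self._cluster_at(mesh, np.arange(144))
        out = assign_maps([cl], self._cfg(), mesh)
        assert out[0].map_label == "NPO"

    def test_too_distant_cluster_unassigned(self):
        mesh = planar_mesh(12, 12)
        shifted = SurfaceMesh(mesh.coordinates + [300.0, 0, 0], mesh.triangles)
        cl = self._cluster_at(shifted, np.arange(144))
        out = assign_maps([cl], self._cfg(), shifted)
        assert out[0].map_label == "unassigned"

    def test_equidistant_tie_breaks_on_label_order(self):
        mesh = planar_mesh(12, 12)
        centered = SurfaceMesh(mesh.coordinates + [44.5 - 5.5, 0, 0],
                               mesh.triangles)  # midway between the centers
        cl = self._cluster_at(centered, np.arange(144))
        out = assign_maps([cl], self._cfg(d_max_mm=60.0), centered)
        assert out[0].map_label == "NPO"  # first label in table order

    def test_missing_center_table_rejected(self):
        with pytest.raises(ValueError, match="center table"):
            assign_maps([], MapAssignmentConfig(reference_centers={}))


class TestBinning:
    def test_eight_bins(self):
        spec = BinningSpec()
        assert spec.n_bins == 8
        np.testing.assert_allclose(spec.centers,
                                   [1.25, 1.75, 2.25, 2.75, 3.25, 3.75, 4.25, 4.75])

    def test_bin_examples(self):
        spec = BinningSpec()
        assert spec.centers[bin_preferred_numerosity([1.25], spec)[0]] == 1.25
        # upper edge is closed: mu = 5 falls in the last bin
        assert bin_preferred_numerosity([5.0], spec)[0] == 7
        assert bin_preferred_numerosity([1.0], spec)[0] == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            bin_preferred_numerosity([0.5])


class TestGeometryCorrelations:
    def _patch(self, mu_of_x):
        mesh = planar_mesh(40, 10)
        x = mesh.coordinates[:, 0]
        mu = mu_of_x(x)
        ids = np.arange(mesh.n_vertices)
        return mesh, mu, ids

    def test_planted_decreasing_area_and_increasing_fwhm(self):
        # geometric mu(x): equal x-extent per doubling -> area shrinks with mu
        mesh, mu, ids = self._patch(
            lambda x: 1.0 * 5.0 ** (x / x.max()))
        omega = 2.0 + 3.0 * mu  # FWHM grows linearly with mu
        res = geometry_correlations(mu, omega, mesh, ids)
        assert res["area_vs_mu_r"] < -0.8
        assert res["fwhm_vs_mu_r"] > 0.99

    def test_pearson_matches_covariance_oracle(self):
        mesh, mu, ids = self._patch(lambda x: 1.0 + 4.0 * (x / x.max()) ** 2)
        omega = 1.0 + mu + 0.1 * np.sin(mu * 5)
        res = geometry_correlations(mu, omega, mesh, ids)
        c, f = res["bin_centers"], res["fwhm_mean"]
        ok = ~np.isnan(f)
        x, y = c[ok], f[ok]
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert res["fwhm_vs_mu_r"] == pytest.approx(r_oracle, abs=1e-12)

    def test_too_few_bins_reported_missing(self):
        mesh = planar_mesh(5, 5)
        mu = np.full(25, 2.2)  # single occupied bin
        res = geometry_correlations(mu, mu, mesh, np.arange(25))
        assert np.isnan(res["area_vs_mu_r"])
        assert np.isnan(res["fwhm_vs_mu_r"])


class TestCoordinatePolynomial:
    def test_design_has_16_columns_for_order_5(self):
        m = CoordinatePolynomialModel(order=5)
        X = np.random.default_rng(0).uniform(size=(30, 3))
        D = m._expand(X, X.mean(axis=0))
        assert D.shape == (30, 16)

    def test_noiseless_linear_gradient_recovered(self):
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(200, 3))
        mu = 1.0 + 0.4 * coords[:, 0]
        res = coordinate_polynomial_model(coords, mu, seed=0)
        assert res["cv_r"] > 0.99
        assert res["mae"] < 0.05

    def test_constant_mu_degenerate(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(size=(50, 3))
        res = coordinate_polynomial_model(coords, np.full(50, 3.0), seed=0)
        assert np.isnan(res["cv_r"])

    def test_too_small_cluster_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            coordinate_polynomial_model(np.zeros((16, 3)), np.zeros(16))

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 5, size=(150, 3))
        mu = 1 + 0.3 * coords[:, 1] + 0.05 * coords[:, 0] ** 2
        a = coordinate_polynomial_model(coords, mu, seed=7)
        b = coordinate_polynomial_model(coords + [123.0, -45.0, 6.0], mu, seed=7)
        np.testing.assert_allclose(a["predictions"], b["predictions"], atol=1e-8)


class TestNumerosityRange:
    def test_constant_values(self):
        res = numerosity_range(np.full(10, 2.0))
        assert res["iqr"] == 0.0
        assert len(res["outliers"]) == 0

    def test_five_point_summary(self):
        res = numerosity_range([1.0, 2.0, 3.0, 4.0, 5.0])
        assert res["median"] == 3.0
        assert res["iqr"] == pytest.approx(2.0)  # linear-interpolation quartiles

    def test_outlier_flagged(self):
        vals = np.array([1.0, 1.1, 1.2, 1.3, 1.4, 5.0])
        res = numerosity_range(vals)
        assert 5.0 in res["outliers"]
        assert res["whisker_high"] < 5.0


class TestMeshIO:
    def test_ascii_round_trip(self, tmp_path):
        mesh = planar_mesh(4, 5)
        path = tmp_path / "mesh.asc"
        write_mesh_ascii(mesh, path)
        back = read_mesh(path)
        np.testing.assert_allclose(back.coordinates, mesh.coordinates, atol=1e-6)
        np.testing.assert_array_equal(back.triangles, mesh.triangles)

    def test_gifti_round_trip(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        mesh = planar_mesh(3, 4)
        img = nib.gifti.GiftiImage(darrays=[
            nib.gifti.GiftiDataArray(mesh.coordinates.astype(np.float32),
                                     intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(mesh.triangles.astype(np.int32),
                                     intent="NIFTI_INTENT_TRIANGLE"),
        ])
        path = tmp_path / "surf.gii"
        nib.save(img, path)
        back = read_mesh(path)
        np.testing.assert_allclose(back.coordinates, mesh.coordinates, atol=1e-5)
        np.testing.assert_array_equal(back.triangles, mesh.triangles)

    def test_bad_triangle_indices_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            SurfaceMesh(np.zeros((3, 3)), np.array([[0, 1, 5]]))
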