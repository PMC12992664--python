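"""Cortical surface geometry of numerosity-selective clusters.

Supra-threshold vertices are grouped into edge-connected clusters on the
triangle mesh, each cluster's area is the summed area of triangles whose
three corners all belong to it, clusters are assigned to known numerotopic
maps by proximity to reference centers, and topographic organization is
quantified by binned area/FWHM statistics and an order-5 coordinate
polynomial model of preferred numerosity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components as _cc
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SurfaceMesh",
    "Cluster",
    "MapAssignmentConfig",
    "BinningSpec",
    "CoordinatePolynomialModel",
    "connected_clusters",
    "cluster_surface_area",
    "assign_maps",
    "bin_preferred_numerosity",
    "geometry_correlations",
    "coordinate_polynomial_model",
    "numerosity_range",
    "read_mesh",
    "write_mesh_ascii",
]


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated cortical surface (pial coordinates in mm)."""

    coordinates: np.ndarray  # (n_vertices, 3)
    triangles: np.ndarray  # (n_triangles, 3) int
    space: str = "native"

    def __post_init__(self) -> None:
        object.__setattr__(self, "coordinates",
                           np.asarray(self.coordinates, dtype=float))
        object.__setattr__(self, "triangles",
                           np.asarray(self.triangles, dtype=int))
        if self.triangles.size and self.triangles.max() >= len(self.coordinates):
            raise ValueError("triangle indices exceed vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.coordinates)

    def edges(self) -> np.ndarray:
        """Undirected unique edges (m, 2)."""
        t = self.triangles
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def triangle_areas(self) -> np.ndarray:
        c = self.coordinates
        a, b, d = (c[self.triangles[:, i]] for i in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, d - a), axis=1)


@dataclass
class Cluster:
    """Edge-connected patch of selected vertices."""

    vertex_ids: np.ndarray
    area_mm2: float = 0.0
    center: np.ndarray | None = None
    map_label: str = "unassigned"

    @property
    def size(self) -> int:
        return len(self.vertex_ids)


@dataclass(frozen=True)
class MapAssignmentConfig:
    """Cluster filtering and map-assignment thresholds.

    Defaults follow the visual analysis (A_min = 50 mm^2, d_max = 25 mm);
    the auditory analysis uses A_min = 25 mm^2 and d_max = 50 mm.
    ``reference_centers`` maps label -> (x, y, z) in the clusters' space.
    """

    a_min_mm2: float = 50.0
    d_max_mm: float = 25.0
    reference_centers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a_min_mm2 <= 0 or self.d_max_mm <= 0:
            raise ValueError("thresholds must be positive")


@dataclass(frozen=True)
class BinningSpec:
    """Preferred-numerosity bins: eight bins of width 0.5 spanning [1, 5]."""

    bin_width: float = 0.5
    lo: float = 1.0
    hi: float = 5.0

    @property
    def edges(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + self.bin_width / 2, self.bin_width)

    @property
    def centers(self) -> np.ndarray:
        e = self.edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def n_bins(self) -> int:
        return len(self.centers)


def connected_clusters(mesh: SurfaceMesh, selected_mask: np.ndarray) -> list[Cluster]:
    """Partition selected vertices into maximal edge-connected components."""
    mask = np.asarray(selected_mask, dtype=bool)
    if len(mask) != mesh.n_vertices:
        raise ValueError("mask length must equal vertex count")
    ids = np.flatnonzero(mask)
    if len(ids) == 0:
        return []
    remap = -np.ones(mesh.n_vertices, dtype=int)
    remap[ids] = np.arange(len(ids))
    e = mesh.edges()
    keep = mask[e[:, 0]] & mask[e[:, 1]]
    e = remap[e[keep]]
    adj = sparse.coo_matrix(
        (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(len(ids), len(ids)))
    n_comp, labels = _cc(adj, directed=False)
    out = []
    for c in range(n_comp):
        vids = ids[labels == c]
        cl = Cluster(vertex_ids=vids)
        cl.area_mm2 = cluster_surface_area(mesh, cl)
        cl.center = mesh.coordinates[vids].mean(axis=0)
        out.append(cl)
    return out


def cluster_surface_area(mesh: SurfaceMesh, cluster: Cluster) -> float:
    """Summed area of triangles whose three corners all lie in the cluster."""
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[np.asarray(cluster.vertex_ids, dtype=int)] = True
    interior = member[mesh.triangles].all(axis=1)
    return float(mesh.triangle_areas()[interior].sum())


def assign_maps(clusters: list[Cluster], cfg: MapAssignmentConfig,
                mesh: SurfaceMesh | None = None) -> list[Cluster]:
    """Label clusters by their nearest reference map center.

    A cluster is retained only if its area reaches ``a_min_mm2`` and at
    least one of its vertices lies within ``d_max_mm`` of some center;
    otherwise it stays 'unassigned'. Among centers within reach, the one
    at minimal vertex-to-center distance wins; exact ties break on label
    order as given in the reference table.
    """
    if not cfg.reference_centers:
        raise ValueError("reference center table is required for map assignment")
    labels = list(cfg.reference_centers)
    centers = np.asarray([cfg.reference_centers[k] for k in labels], dtype=float)
    for cl in clusters:
        cl.map_label = "unassigned"
        if cl.area_mm2 < cfg.a_min_mm2:
            continue
        coords = (mesh.coordinates[cl.vertex_ids] if mesh is not None
                  else np.atleast_2d(cl.center))
        d = np.linalg.norm(coords[:, None, :] - centers[None, :, :], axis=2)
        dmin = d.min(axis=0)  # per center
        best = int(np.argmin(dmin))  # first label wins ties
        if dmin[best] <= cfg.d_max_mm:
            cl.map_label = labels[best]
    return clusters


def bin_preferred_numerosity(mu_values, spec: BinningSpec = BinningSpec()) -> np.ndarray:
    """Bin index per vertex; bins are [edge, edge) with the last closed at 5."""
    mu = np.asarray(mu_values, dtype=float)
    if np.any((mu < spec.lo) | (mu > spec.hi)):
        raise ValueError(f"mu outside [{spec.lo}, {spec.hi}] should have been filtered")
    idx = np.digitize(mu, spec.edges) - 1
    return np.clip(idx, 0, spec.n_bins - 1)


def _pearson(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(stats.pearsonr(x, y)[0])


def geometry_correlations(mu_values, omega_values, mesh: SurfaceMesh,
                          vertex_ids, spec: BinningSpec = BinningSpec()) -> dict:
    """Binned area and tuning-width statistics against preferred numerosity.

    Triangles fully inside the supra-threshold set are assigned to a bin by
    the mean preferred numerosity of their three corners; their areas are
    summed per bin. FWHM is averaged per vertex bin with its standard
    error. Pearson correlations over non-empty bin centers plus linear
    (and, for area, quadratic) polynomial fits are reported.
    """
    mu_values = np.asarray(mu_values, float)
    omega_values = np.asarray(omega_values, float)
    vertex_ids = np.asarray(vertex_ids, int)
    mu_full = np.full(mesh.n_vertices, np.nan)
    mu_full[vertex_ids] = mu_values
    member = np.zeros(mesh.n_vertices, dtype=bool)
    member[vertex_ids] = True

    interior = member[mesh.triangles].all(axis=1)
    tri_mu = mu_full[mesh.triangles[interior]].mean(axis=1)
    tri_area = mesh.triangle_areas()[interior]
    tri_mu = np.clip(tri_mu, spec.lo, spec.hi)
    tri_bin = bin_preferred_numerosity(tri_mu, spec)
    area = np.bincount(tri_bin, weights=tri_area, minlength=spec.n_bins)

    v_bin = bin_preferred_numerosity(np.clip(mu_values, spec.lo, spec.hi), spec)
    counts = np.bincount(v_bin, minlength=spec.n_bins)
    fwhm_mean = np.full(spec.n_bins, np.nan)
    fwhm_se = np.full(spec.n_bins, np.nan)
    for b in range(spec.n_bins):
        w = omega_values[v_bin == b]
        if len(w):
            fwhm_mean[b] = w.mean()
            fwhm_se[b] = w.std(ddof=1) / np.sqrt(len(w)) if len(w) > 1 else 0.0

    nz_area = area > 0
    nz_fwhm = ~np.isnan(fwhm_mean)
    res = {
        "bin_centers": spec.centers,
        "area_mm2": area,
        "fwhm_mean": fwhm_mean,
        "fwhm_se": fwhm_se,
        "vertex_counts": counts,
        "area_vs_mu_r": (_pearson(spec.centers[nz_area], area[nz_area])
                         if nz_area.sum() >= 3 else np.nan),
        "fwhm_vs_mu_r": (_pearson(spec.centers[nz_fwhm], fwhm_mean[nz_fwhm])
                         if nz_fwhm.sum() >= 3 else np.nan),
    }
    if nz_area.sum() >= 3:
        res["area_linear_fit"] = np.polyfit(spec.centers[nz_area], area[nz_area], 1)
        res["area_quadratic_fit"] = np.polyfit(spec.centers[nz_area], area[nz_area], 2)
    if nz_fwhm.sum() >= 3:
        res["fwhm_linear_fit"] = np.polyfit(spec.centers[nz_fwhm],
                                            fwhm_mean[nz_fwhm], 1)
    return res


class CoordinatePolynomialModel(RegressorMixin, BaseEstimator):
    """Pure-power polynomial regression of preferred numerosity on surface
    coordinates.

    mu(x, y, z) = b0 + sum_k (b_xk x^k + b_yk y^k + b_zk z^k), k = 1..order,
    with coordinates mean-centered at fit time (no cross terms; 1 + 3*order
    design columns).
    """

    def __init__(self, order: int = 5):
        self.order = order

    def _expand(self, X, center):
        X = np.asarray(X, dtype=float) - center
        cols = [np.ones(len(X))]
        for k in range(1, self.order + 1):
            cols.extend(X[:, j] ** k for j in range(3))
        return np.column_stack(cols)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[1] != 3:
            raise ValueError("X must be (n_vertices, 3) coordinates")
        self.center_ = X.mean(axis=0)
        D = self._expand(X, self.center_)
        self.coef_, *_ = np.linalg.lstsq(D, y, rcond=None)
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self._expand(X, self.center_) @ self.coef_


def coordinate_polynomial_model(coords, mu_values, order: int = 5,
                                n_folds: int = 10, seed: int = 0) -> dict:
    """10-fold cross-validated coordinate-polynomial topography model.

    Folds are a seeded random partition of vertices. Returns the Pearson
    correlation between cross-validated predictions and actual preferred
    numerosity (cv_r), the mean absolute error and the predictions.
    """
    coords = np.asarray(coords, dtype=float)
    mu_values = np.asarray(mu_values, dtype=float)
    n_cols = 1 + 3 * order
    if len(coords) <= n_cols:
        raise ValueError(
            f"cluster too small: need > {n_cols} vertices for order {order}")
    pred = np.full(len(mu_values), np.nan)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for train, test in kf.split(coords):
        m = CoordinatePolynomialModel(order=order).fit(coords[train], mu_values[train])
        pred[test] = m.predict(coords[test])
    if np.std(mu_values) == 0:
        cv_r = np.nan  # degenerate: constant preferred numerosity
    else:
        cv_r = _pearson(pred, mu_values)
    mae = float(np.mean(np.abs(pred - mu_values)))
    return {"cv_r": cv_r, "mae": mae, "predictions": pred}


def numerosity_range(mu_values) -> dict:
    """Boxplot five-number summary with the 1.5 IQR whisker rule.

    Quartiles use linear interpolation. Whiskers extend to the most extreme
    data points within 1.5 IQR of the box; points beyond are outliers.
    """
    mu = np.sort(np.asarray(mu_values, dtype=float))
    q1, med, q3 = np.percentile(mu, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = mu[(mu >= lo_fence) & (mu <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "iqr": float(iqr),
        "whisker_low": float(inside.min()), "whisker_high": float(inside.max()),
        "outliers": mu[(mu < lo_fence) | (mu > hi_fence)],
    }


# -- mesh I/O ---------------------------------------------------------------

def read_mesh(path, space: str = "native") -> SurfaceMesh:
    """Read a surface from GIFTI (.gii, via nibabel) or plain ASCII.

    The ASCII format is: a header line "n_vertices n_triangles", then one
    "x y z" line per vertex and one "i j k" line per triangle.
    """
    path = str(path)
    if path.endswith(".gii"):
        import nibabel as nib

        img = nib.load(path)
        coords = img.darrays[0].data
        tris = img.darrays[1].data
        return SurfaceMesh(coords, tris, space=space)
    with open(path) as fh:
        nv, nt = map(int, fh.readline().split())
        coords = np.array([fh.readline().split() for _ in range(nv)], dtype=float)
        tris = np.array([fh.readline().split() for _ in range(nt)], dtype=int)
    return SurfaceMesh(coords, tris, space=space)


def write_mesh_ascii(mesh: SurfaceMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{mesh.n_vertices} {len(mesh.triangles)}\n")
        for x, y, z in mesh.coordinates:
            fh.write(f"{x:.6f} {y:.6f} {z:.6f}\n")
        for i, j, k in mesh.triangles:
            fh.write(f"{i} {j} {k}\n")
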