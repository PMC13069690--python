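"""Boundary detection and region geometry.

The pipeline for a cluster is: (1) remove spatial outliers by mean k-NN
distance against a threshold tau, (2) split the survivors into spatially
contiguous subregions (DBSCAN or k-means), (3) wrap each subregion in a
concave-hull boundary polygon. Rings (buffered annuli), point-in-region
extraction, composition statistics and perimeter splitting all operate on the
resulting polygons.

All geometry lives in the platform's planar units (e.g. µm); polygons are
oriented counterclockwise, and point-in-polygon tests are boundary-inclusive
(a cell exactly on a boundary counts as inside).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import LineString, MultiPoint, Polygon, mapping, shape
from shapely.geometry.polygon import orient
from sklearn.cluster import DBSCAN, KMeans
from sklearn.neighbors import NearestNeighbors

from .data import validate_cell_table
from .errors import GeometryError, InsufficientDataError, ParameterError, ValidationError


# ---------------------------------------------------------------------------
# outlier removal


def remove_spatial_outliers(
    cells: pd.DataFrame, tau: float, k_outlier: int = 5
) -> pd.DataFrame:
    """Flag spatial outliers by mean distance to the k nearest neighbors.

    For each cell c the mean Euclidean distance d̄_c to its ``k_outlier``
    nearest neighbors (self excluded) is computed; cells with d̄_c > tau are
    flagged for removal.

    Returns a report frame with columns ``cell``, ``mean_knn_dist``, ``keep``
    in input order; ``k_outlier`` and ``tau`` are recorded in ``.attrs``.
    """
    validate_cell_table(cells)
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    n = len(cells)
    if n <= k_outlier:
        raise ParameterError(
            f"selection has {n} cells but k_outlier={k_outlier} requires more"
        )
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    nn = NearestNeighbors(n_neighbors=k_outlier + 1).fit(xy)
    dist, _ = nn.kneighbors(xy)
    mean_d = dist[:, 1:].mean(axis=1)  # column 0 is self (distance 0)
    report = pd.DataFrame(
        {"cell": cells["cell"].to_numpy(), "mean_knn_dist": mean_d, "keep": mean_d <= tau}
    )
    report.attrs.update(k_outlier=k_outlier, tau=tau)
    return report


# ---------------------------------------------------------------------------
# subregions


def detect_subregions(
    points: np.ndarray,
    method: str = "dbscan",
    eps: float | None = None,
    n_centers: int | None = None,
    min_pts: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Label spatially contiguous subregions of a point cloud.

    DBSCAN labels noise points -1 (they are excluded from boundary
    construction downstream); k-means is seeded for determinism.
    """
    points = np.asarray(points, dtype=float)
    if method == "dbscan":
        if eps is None or eps <= 0:
            raise ParameterError("dbscan requires eps > 0")
        labels = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(points)
        if (labels == -1).all():
            raise GeometryError(
                "all points classified as DBSCAN noise; increase eps"
            )
        return labels
    if method == "kmeans":
        if n_centers is None or not 1 <= n_centers <= len(points):
            raise ParameterError(
                f"kmeans requires 1 <= n_centers <= {len(points)}"
            )
        km = KMeans(n_clusters=n_centers, random_state=seed, n_init=10)
        return km.fit_predict(points)
    raise ParameterError(f"unknown subregion method '{method}'")


# ---------------------------------------------------------------------------
# concave hull


def build_boundary(
    points: np.ndarray, concavity: float = 2.0, length_threshold: float = 0.0
) -> Polygon:
    """Concave-hull boundary polygon around a point cloud.

    ``concavity`` controls smoothness: small values hug the points, large
    values approach the convex hull (the limit concavity -> inf is exactly
    the convex hull). ``length_threshold`` optionally smooths away boundary
    detail shorter than the given length while preserving containment of all
    input points.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 3:
        raise GeometryError(f"need >= 3 points to build a boundary, got {len(points)}")
    if concavity < 0:
        raise ParameterError("concavity must be >= 0")
    mp = MultiPoint(points)
    if not np.isfinite(concavity):
        hull = mp.convex_hull
    else:
        ratio = concavity / (1.0 + concavity)
        hull = shapely.concave_hull(mp, ratio=ratio, allow_holes=False)
    if hull.geom_type != "Polygon" or hull.area <= 0:
        raise GeometryError("degenerate geometry: points are collinear or coincident")
    if length_threshold > 0:
        smoothed = hull.simplify(length_threshold, preserve_topology=True)
        merged = hull.union(smoothed)
        if merged.geom_type == "Polygon" and merged.area > 0:
            hull = merged
    return orient(hull, sign=1.0)


@dataclass
class BoundarySet:
    """Boundary polygons for one cluster, numbered by descending area.

    Region 1 is the largest ("primary") polygon. ``params`` records the
    detection parameters that produced the set.
    """

    polygons: list[Polygon]
    region_ids: list[int]
    params: dict = field(default_factory=dict)

    @property
    def primary(self) -> Polygon:
        return self.polygons[0]

    def __len__(self) -> int:
        return len(self.polygons)


def get_boundary(
    cells: pd.DataFrame,
    cluster,
    tau: float,
    k_outlier: int = 5,
    method: str = "dbscan",
    eps: float | None = None,
    n_centers: int | None = None,
    min_pts: int = 5,
    concavity: float = 2.0,
    length_threshold: float = 0.0,
    seed: int = 0,
) -> BoundarySet:
    """Full boundary-detection pipeline for one cluster.

    Outlier removal (once per cluster, before subregion detection), then
    subregion detection, then one concave hull per subregion; regions are
    renumbered 1..R by descending polygon area.
    """
    validate_cell_table(cells)
    labels = cells["cluster"].astype(str)
    if str(cluster) not in set(labels):
        raise ValidationError(f"unknown cluster '{cluster}'")
    sel = cells.loc[labels == str(cluster)].reset_index(drop=True)
    try:
        report = remove_spatial_outliers(sel, tau=tau, k_outlier=k_outlier)
    except Exception as exc:
        raise type(exc)(f"outlier-removal stage: {exc}") from exc
    kept = sel.loc[report["keep"].to_numpy()].reset_index(drop=True)
    pts = kept[["x", "y"]].to_numpy(dtype=float)
    try:
        sub = detect_subregions(
            pts, method=method, eps=eps, n_centers=n_centers, min_pts=min_pts, seed=seed
        )
    except Exception as exc:
        raise type(exc)(f"subregion stage: {exc}") from exc
    polys = []
    for lab in sorted(set(sub) - {-1}):
        try:
            polys.append(
                build_boundary(pts[sub == lab], concavity=concavity,
                               length_threshold=length_threshold)
            )
        except GeometryError:
            continue  # a 2-point "subregion" has no boundary
    if not polys:
        raise GeometryError("boundary stage: no subregion yields a valid polygon")
    polys.sort(key=lambda p: p.area, reverse=True)
    params = dict(
        cluster=str(cluster), k_outlier=k_outlier, tau=tau, method=method,
        eps=eps, n_centers=n_centers, min_pts=min_pts, concavity=concavity,
        length_threshold=length_threshold, seed=seed,
    )
    return BoundarySet(polys, list(range(1, len(polys) + 1)), params)


# ---------------------------------------------------------------------------
# rings


@dataclass
class RingRegion:
    """An inner boundary polygon and its outward buffer.

    The ring (annulus) is the set difference outer minus inner; membership is
    "inside outer and not inside inner" with boundary-inclusive tests. The
    buffer uses round joins (true Minkowski offset).
    """

    inner: Polygon
    outer: Polygon
    dist: float


def build_ring_region(boundary: Polygon, dist: float = 100.0) -> RingRegion:
    """Buffer a boundary polygon outward by ``dist`` (default 100 units)."""
    if dist <= 0:
        raise ParameterError(f"buffer dist must be > 0, got {dist}")
    if boundary.is_empty or boundary.area <= 0:
        raise GeometryError("cannot buffer a degenerate boundary")
    outer = boundary.buffer(dist, quad_segs=32, join_style="round")
    return RingRegion(inner=orient(boundary, 1.0), outer=orient(outer, 1.0), dist=dist)


def cells_inside(cells: pd.DataFrame, region) -> pd.DataFrame:
    """Cells inside a polygon or ring, input order preserved.

    Polygon membership is boundary-inclusive (`covers`); for a
    :class:`RingRegion` the test is inside-outer AND NOT inside-inner, so the
    inner region and the ring partition the outer region.
    """
    validate_cell_table(cells)
    pts = shapely.points(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
    if isinstance(region, RingRegion):
        mask = shapely.covers(region.outer, pts) & ~shapely.covers(region.inner, pts)
    else:
        mask = shapely.covers(region, pts)
    return cells.loc[mask].reset_index(drop=True)


def stats_cells_inside(subset: pd.DataFrame) -> pd.DataFrame:
    """Cluster composition of a cell subset.

    Returns (cluster, count, proportion) sorted by descending proportion,
    ties broken by label order; proportions sum to 1.
    """
    if len(subset) == 0:
        raise InsufficientDataError("empty region: no cells to summarize")
    counts = subset["cluster"].astype(str).value_counts()
    table = pd.DataFrame(
        {"cluster": counts.index, "count": counts.to_numpy(),
         "proportion": counts.to_numpy() / counts.sum()}
    )
    table = table.sort_values(
        ["proportion", "cluster"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table


def compare_compositions(
    tables_a: list[pd.DataFrame], tables_b: list[pd.DataFrame]
) -> pd.DataFrame:
    """Per-cluster Welch t-test of ring compositions between two conditions.

    Each input list holds one composition table per ring (as produced by
    :func:`stats_cells_inside`); clusters absent from a ring contribute
    proportion 0. Returns per cluster the mean proportion per condition, the
    two-sided Welch t statistic and its p-value.
    """
    if len(tables_a) < 2 or len(tables_b) < 2:
        raise InsufficientDataError(
            "need >= 2 rings per condition for a t-test "
            f"(got {len(tables_a)} vs {len(tables_b)})"
        )
    labels = sorted(
        {c for t in tables_a + tables_b for c in t["cluster"].astype(str)}
    )

    def props(tables, lab):
        return np.array(
            [t.set_index(t["cluster"].astype(str))["proportion"].get(lab, 0.0)
             for t in tables]
        )

    rows = []
    for lab in labels:
        a, b = props(tables_a, lab), props(tables_b, lab)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            t, p = (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {"cluster": lab, "mean_a": a.mean(), "mean_b": b.mean(),
             "t": float(t), "p": float(p)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# perimeter splitting


@dataclass
class BoundaryEdge:
    """One directed stretch of a boundary polygon's perimeter."""

    edge_id: int
    coords: np.ndarray  # open vertex sequence, counterclockwise
    parent_region: int = 1

    @property
    def line(self) -> LineString:
        return LineString(self.coords)

    @property
    def length(self) -> float:
        return self.line.length


def split_boundary_by_anchors(
    boundary: Polygon, anchors, parent_region: int = 1
) -> list[BoundaryEdge]:
    """Cut a polygon perimeter into directional edges at anchor points.

    Each anchor snaps to its nearest polygon vertex; the perimeter is cut at
    the snapped vertices in counterclockwise order starting from the vertex
    nearest the first anchor. Edge i runs from cut i to cut i+1 (inclusive of
    both endpoints), so edge lengths sum to the polygon perimeter.
    """
    anchors = np.asarray(anchors, dtype=float)
    if len(anchors) < 2:
        raise ParameterError("need >= 2 anchors to split a perimeter")
    ring = orient(boundary, 1.0).exterior
    verts = np.asarray(ring.coords)[:-1]  # drop closing duplicate
    snapped = []
    for a in anchors:
        d = np.hypot(verts[:, 0] - a[0], verts[:, 1] - a[1])
        snapped.append(int(np.argmin(d)))
    if len(set(snapped)) < len(snapped):
        raise ParameterError("ambiguous anchors: two anchors snap to the same vertex")
    start = snapped[0]
    order = sorted(snapped, key=lambda i: (i - start) % len(verts))
    edges = []
    for e, i in enumerate(order, start=1):
        j = order[(e) % len(order)]
        if j > i:
            seq = verts[i : j + 1]
        else:  # wrap around the ring
            seq = np.vstack([verts[i:], verts[: j + 1]])
        edges.append(BoundaryEdge(edge_id=e, coords=seq, parent_region=parent_region))
    return edges


# ---------------------------------------------------------------------------
# GeoJSON I/O


def to_geojson(obj, path: str | Path) -> None:
    """Serialize a BoundarySet, RingRegion, polygon or edges to GeoJSON."""
    if isinstance(obj, BoundarySet):
        feats = [
            {"type": "Feature", "properties": {"region": rid, **{
                k: v for k, v in obj.params.items() if v is not None}},
             "geometry": mapping(poly)}
            for rid, poly in zip(obj.region_ids, obj.polygons)
        ]
    elif isinstance(obj, RingRegion):
        feats = [
            {"type": "Feature", "properties": {"role": "inner"}, "geometry": mapping(obj.inner)},
            {"type": "Feature", "properties": {"role": "outer", "dist": obj.dist},
             "geometry": mapping(obj.outer)},
        ]
    elif isinstance(obj, list) and obj and isinstance(obj[0], BoundaryEdge):
        feats = [
            {"type": "Feature",
             "properties": {"edge": e.edge_id, "region": e.parent_region},
             "geometry": mapping(e.line)}
            for e in obj
        ]
    else:  # bare shapely geometry
        feats = [{"type": "Feature", "properties": {}, "geometry": mapping(obj)}]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats}, indent=1)
    )


def from_geojson(path: str | Path) -> list:
    """Read geometries back from a GeoJSON FeatureCollection."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in doc["features"]]
    return [shape(doc.get("geometry", doc))]
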