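"""Distance-decay spatial weights.

Each cell in a selection is assigned a weight in (0, 1] reflecting its
proximity to a reference — either the centroid of a cell population or a
boundary geometry (polygon outline or perimeter edge). The pipeline is

    raw distance  ->  min-max normalization  ->  decay kernel

with four kernels applied to the normalized distance d̃ in [0, 1]:

    inverse     w = 1 / (1 + d̃)          range [0.5, 1]
    gaussian    w = exp(-d̃² / (2σ²))     range (0, 1]
    linear      w = 1 - d̃                range [0, 1]
    quadratic   w = (1 - d̃)²             range [0, 1]

A weight of 1 always marks the closest cell (a cell exactly on a boundary
geometry gets weight 1 under every kernel). Distances to polygons are
measured to the outline itself, so cells in the polygon interior still get
positive distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Polygon
from shapely.geometry.base import BaseGeometry

from .data import validate_cell_table
from .errors import GeometryError, ParameterError
from .geometry import BoundaryEdge

DECAY_KINDS = ("inverse", "gaussian", "linear", "quadratic")


@dataclass
class SpatialWeights:
    """Per-cell weight provenance: raw distance, normalized distance, weight.

    ``frame`` has columns ``cell``, ``raw_dist``, ``norm_dist``, ``weight``.
    """

    frame: pd.DataFrame
    decay: str
    sigma: float = 0.3
    reference: str = ""
    attrs: dict = field(default_factory=dict)

    @property
    def cells(self) -> pd.Index:
        return pd.Index(self.frame["cell"].astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.frame["weight"].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SpatialWeights":
        frame = pd.read_csv(path, sep="\t")
        for col in ("cell", "raw_dist", "norm_dist", "weight"):
            if col not in frame.columns:
                raise ParameterError(f"weights file missing column '{col}'")
        frame["cell"] = frame["cell"].astype(str)
        return cls(frame=frame, decay="unknown")


def distance_to_centroid(
    cells: pd.DataFrame, reference_cells: pd.DataFrame
) -> np.ndarray:
    """Euclidean distance of each query cell to the reference centroid s0.

    The centroid is the arithmetic mean of the reference coordinates.
    """
    if len(reference_cells) == 0:
        raise ParameterError("reference cell set is empty")
    s0 = reference_cells[["x", "y"]].to_numpy(dtype=float).mean(axis=0)
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    return np.hypot(xy[:, 0] - s0[0], xy[:, 1] - s0[1])


def distance_to_geometry(cells: pd.DataFrame, geometry) -> np.ndarray:
    """Shortest Euclidean distance from each cell to a boundary curve.

    Polygons are reduced to their exterior outline; edges to their polyline.
    Distance is to the continuous curve, not just its vertices; a point on
    the curve yields 0.
    """
    curve = _as_curve(geometry)
    pts = shapely.points(cells["x"].to_numpy(float), cells["y"].to_numpy(float))
    return shapely.distance(pts, curve)


def _as_curve(geometry) -> BaseGeometry:
    if isinstance(geometry, BoundaryEdge):
        curve = geometry.line
    elif isinstance(geometry, Polygon):
        curve = geometry.exterior
    elif isinstance(geometry, BaseGeometry):
        curve = geometry.boundary if geometry.area > 0 else geometry
    else:
        curve = LineString(np.asarray(geometry, dtype=float))
    if curve.is_empty or curve.length <= 0:
        raise ParameterError("degenerate (zero-length) reference geometry")
    return curve


def normalize_minmax(d: np.ndarray) -> np.ndarray:
    """Min-max normalize raw distances to [0, 1].

    If all distances are equal the output is all zeros (every cell is
    maximally close), the convention used throughout for degenerate
    selections.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ParameterError("no distances to normalize")
    lo, hi = d.min(), d.max()
    if hi == lo:
        return np.zeros_like(d)
    return (d - lo) / (hi - lo)


def apply_decay(norm_dist: np.ndarray, decay: str, sigma: float = 0.3) -> np.ndarray:
    """Map normalized distances to weights with one of the four kernels."""
    d = np.asarray(norm_dist, dtype=float)
    if decay == "inverse":
        return 1.0 / (1.0 + d)
    if decay == "gaussian":
        if sigma <= 0:
            raise ParameterError(f"gaussian decay requires sigma > 0, got {sigma}")
        return np.exp(-(d ** 2) / (2.0 * sigma ** 2))
    if decay == "linear":
        return 1.0 - d
    if decay == "quadratic":
        return (1.0 - d) ** 2
    raise ParameterError(f"unknown decay kind '{decay}' (expected one of {DECAY_KINDS})")


def _compose(cells, raw, decay, sigma, reference) -> SpatialWeights:
    norm = normalize_minmax(raw)
    w = apply_decay(norm, decay, sigma)
    frame = pd.DataFrame(
        {"cell": cells["cell"].astype(str).to_numpy(),
         "raw_dist": np.asarray(raw, float),
         "norm_dist": norm, "weight": w}
    )
    return SpatialWeights(frame=frame, decay=decay, sigma=sigma, reference=reference)


def compute_centroid_weights(
    cells: pd.DataFrame,
    reference_cells: pd.DataFrame,
    decay: str = "inverse",
    sigma: float = 0.3,
) -> SpatialWeights:
    """Weights from distance to the centroid of a reference population."""
    validate_cell_table(cells)
    raw = distance_to_centroid(cells, reference_cells)
    s0 = reference_cells[["x", "y"]].to_numpy(dtype=float).mean(axis=0)
    return _compose(cells, raw, decay, sigma, f"centroid({s0[0]:.6g},{s0[1]:.6g})")


def compute_boundary_weights(
    cells: pd.DataFrame,
    geometry,
    decay: str = "inverse",
    sigma: float = 0.3,
) -> SpatialWeights:
    """Weights from shortest distance to a boundary outline or edge."""
    validate_cell_table(cells)
    raw = distance_to_geometry(cells, geometry)
    ref = "edge" if isinstance(geometry, BoundaryEdge) else "boundary"
    if isinstance(geometry, BoundaryEdge):
        ref = f"edge:{geometry.edge_id}"
    return _compose(cells, raw, decay, sigma, ref)
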