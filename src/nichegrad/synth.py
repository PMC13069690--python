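"""Seeded synthetic-tissue generator.

Emits coordinate tables, log-scale expression matrices and full ground truth
for layouts that emulate the structures boundary-aware analysis targets:

* ``two_blobs`` — two well-separated Gaussian blobs (disjoint subregions of
  distinct clusters);
* ``nested_disc`` — an inner disc cluster surrounded by an annulus cluster
  (boundary/ring geometry);
* ``half_planes`` — a straight interface between two clusters;
* ``zones_1d`` — three vertical zones (a zonation-gradient analog).

Expression is Gaussian noise on the log scale around planted structure, then
zero-inflated (dropout) and clamped at zero — matching the modeling
assumption that data arrive already normalized and log-transformed, not a
count-level sequencing simulation. Marker genes add ``marker_effect`` inside
their cluster; gradient genes follow ``gradient_slope`` times a signed
normalized spatial covariate (distance to the layout's generating boundary
or centroid); null genes are pure noise. Everything is reproducible from the
config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .data import ExpressionMatrix, write_coords, write_expression_mtx
from .errors import ParameterError

LAYOUTS = ("two_blobs", "nested_disc", "half_planes", "zones_1d")


@dataclass
class SyntheticTissueConfig:
    """Study conditions for one synthetic tissue."""

    n_cells: int = 400
    layout: str = "nested_disc"
    domain: tuple[float, float, float, float] = (0.0, 0.0, 1000.0, 1000.0)
    n_marker_genes: int = 12
    n_gradient_genes: int = 12
    n_null_genes: int = 36
    baseline: float = 1.0
    marker_effect: float = 2.0
    gradient_slope: float = 2.0
    noise_sd: float = 0.5
    dropout_rate: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise ParameterError(f"unknown layout '{self.layout}'")
        if self.n_cells < 20:
            raise ParameterError("n_cells must be >= 20")
        if self.n_marker_genes + self.n_gradient_genes + self.n_null_genes < 1:
            raise ParameterError("need at least one gene")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ParameterError("noise_sd must be > 0")


@dataclass
class GroundTruth:
    """Planted structure: per-gene category, per-cell zone, geometry, covariate."""

    gene_info: pd.DataFrame        # gene, category {marker,gradient,null}, target
    cell_zone: pd.Series           # true cluster per cell, indexed by cell id
    boundary                     : object  # shapely geometry generating the gradient
    covariate: np.ndarray          # normalized spatial covariate t in [0, 1]


# named fixture configurations (documented seeds, reproducible acceptance runs)
FIXTURES: dict[str, SyntheticTissueConfig] = {
    "small": SyntheticTissueConfig(
        n_cells=400, layout="nested_disc", n_marker_genes=12,
        n_gradient_genes=12, n_null_genes=36, seed=11,
    ),
    "medium": SyntheticTissueConfig(
        n_cells=5000, layout="nested_disc", n_marker_genes=60,
        n_gradient_genes=60, n_null_genes=180, seed=12,
    ),
}


def fixture_config(name: str) -> SyntheticTissueConfig:
    if name not in FIXTURES:
        raise ParameterError(f"unknown fixture '{name}' (have {sorted(FIXTURES)})")
    return FIXTURES[name]


def _coordinates(cfg: SyntheticTissueConfig, rng: np.random.Generator):
    """Sample coordinates, cluster labels, covariate t and generating geometry."""
    x0, y0, x1, y1 = cfg.domain
    w, h = x1 - x0, y1 - y0
    cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
    n = cfg.n_cells
    if cfg.layout == "two_blobs":
        n_a = n // 2
        spread = min(w, h) / 10
        a = rng.normal([x0 + w / 4, cy], spread, size=(n_a, 2))
        b = rng.normal([x0 + 3 * w / 4, cy], spread, size=(n - n_a, 2))
        xy = np.vstack([a, b])
        zone = np.array(["A"] * n_a + ["B"] * (n - n_a))
        ref = Point(x0 + w / 4, cy)  # centroid of blob A
        d = np.hypot(xy[:, 0] - ref.x, xy[:, 1] - ref.y)
    elif cfg.layout == "nested_disc":
        r_out = min(w, h) / 2 * 0.95
        r_in = r_out * 0.55
        theta = rng.uniform(0, 2 * np.pi, n)
        r = r_out * np.sqrt(rng.uniform(0, 1, n))
        xy = np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])
        zone = np.where(r <= r_in, "A", "B")
        ref = Point(cx, cy).buffer(r_in, quad_segs=64).exterior  # generating circle
        d = np.abs(r - r_in)  # distance to the inner-disc boundary
    elif cfg.layout == "half_planes":
        xy = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
        zone = np.where(xy[:, 0] <= cx, "A", "B")
        ref = LineString([(cx, y0), (cx, y1)])
        d = np.abs(xy[:, 0] - cx)
    else:  # zones_1d
        xy = np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])
        thirds = np.digitize(xy[:, 0], [x0 + w / 3, x0 + 2 * w / 3])
        zone = np.array(["zone1", "zone2", "zone3"])[thirds]
        ref = LineString([(x0, y0), (x0, y1)])  # left face: zonation axis origin
        d = xy[:, 0] - x0
    t = (d - d.min()) / (d.max() - d.min())
    return xy, zone, t, ref


def generate_tissue(
    config: SyntheticTissueConfig,
) -> tuple[pd.DataFrame, ExpressionMatrix, GroundTruth]:
    """Generate one synthetic tissue: cell table, expression, ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    xy, zone, t, ref = _coordinates(cfg, rng)
    n = cfg.n_cells
    cell_ids = [f"c{i + 1}" for i in range(n)]
    cells = pd.DataFrame(
        {"x": xy[:, 0], "y": xy[:, 1], "cell": cell_ids, "cluster": zone}
    )

    clusters = sorted(set(zone))
    genes, cats, targets, rows = [], [], [], []
    for i in range(cfg.n_marker_genes):
        cl = clusters[i % len(clusters)]
        mean = cfg.baseline + cfg.marker_effect * (zone == cl).astype(float)
        genes.append(f"marker_{cl}_{i + 1}")
        cats.append("marker")
        targets.append(cl)
        rows.append(mean)
    for i in range(cfg.n_gradient_genes):
        sign = 1 if i % 2 == 0 else -1
        # ramp up or down across the covariate; means stay non-negative pre-noise
        slope = abs(cfg.gradient_slope)
        mean = cfg.baseline + (slope * t if sign > 0 else slope * (1.0 - t))
        genes.append(f"grad_{'up' if sign > 0 else 'down'}_{i + 1}")
        cats.append("gradient")
        targets.append(str(sign))
        rows.append(mean)
    for i in range(cfg.n_null_genes):
        genes.append(f"null_{i + 1}")
        cats.append("null")
        targets.append("")
        rows.append(np.full(n, cfg.baseline))

    Y = np.vstack(rows) + rng.normal(0.0, cfg.noise_sd, size=(len(rows), n))
    if cfg.dropout_rate > 0:
        Y[rng.uniform(size=Y.shape) < cfg.dropout_rate] = 0.0
    Y = np.clip(Y, 0.0, None)

    expr = ExpressionMatrix(pd.Index(genes), pd.Index(cell_ids), Y)
    truth = GroundTruth(
        gene_info=pd.DataFrame({"gene": genes, "category": cats, "target": targets}),
        cell_zone=pd.Series(zone, index=pd.Index(cell_ids, name="cell"), name="zone"),
        boundary=ref,
        covariate=t,
    )
    return cells, expr, truth


def write_tissue(outdir: str | Path, cells: pd.DataFrame, expr: ExpressionMatrix,
                 truth: GroundTruth) -> None:
    """Write coordinate TSV, MTX triplet and ground-truth TSVs to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_coords(cells, outdir / "coords.tsv")
    write_expression_mtx(expr, outdir / "expression.mtx",
                         outdir / "genes.txt", outdir / "cells.txt")
    truth.gene_info.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    truth.cell_zone.reset_index().to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
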