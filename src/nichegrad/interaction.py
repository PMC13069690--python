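"""Cluster-to-cluster spatial interaction counts.

For every cell, its k nearest spatial neighbors (Euclidean, self excluded)
are found and their cluster identities tabulated, giving a matrix M where
M[i, j] counts how often a cell of cluster i has a cluster-j cell among its
k neighbors. Each cell contributes exactly k votes, so row i always sums to
k x (number of cells in cluster i).

Neighbors are computed over exactly the cell table passed in; to analyse a
ring-localized population, pass the ring subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .data import validate_cell_table
from .errors import ParameterError


@dataclass
class InteractionMatrix:
    """kNN adjacency counts between clusters.

    ``counts`` is a cluster x cluster integer DataFrame (rows = focal
    cluster, columns = neighbor cluster) in sorted label order.
    """

    counts: pd.DataFrame
    k_neighbors: int
    scaled: pd.DataFrame | None = None
    scale_mode: str | None = None

    @property
    def clusters(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "cluster"
        out.to_csv(path, sep="\t")


def compute_interaction_matrix(
    cells: pd.DataFrame, k_neighbors: int = 10
) -> InteractionMatrix:
    """Count neighbor-cluster identities over each cell's k nearest neighbors."""
    validate_cell_table(cells)
    n = len(cells)
    if n <= k_neighbors:
        raise ParameterError(
            f"need more than k_neighbors={k_neighbors} cells, got {n}"
        )
    xy = cells[["x", "y"]].to_numpy(dtype=float)
    labels = cells["cluster"].astype(str).to_numpy()
    order = sorted(set(labels))
    code = {c: i for i, c in enumerate(order)}
    lab_idx = np.array([code[c] for c in labels])

    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(xy)
    _, idx = nn.kneighbors(xy)
    # drop self wherever it appears among the k+1 hits (coincident points can
    # push it out of column 0)
    neigh = np.empty((n, k_neighbors), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i][:k_neighbors]
        if len(row) < k_neighbors:  # self absent from hits: take first k
            row = idx[i][:k_neighbors]
        neigh[i] = row

    counts = np.zeros((len(order), len(order)), dtype=int)
    np.add.at(counts, (np.repeat(lab_idx, k_neighbors), lab_idx[neigh.ravel()]), 1)
    frame = pd.DataFrame(counts, index=order, columns=order)
    return InteractionMatrix(counts=frame, k_neighbors=k_neighbors)


def scale_interaction_matrix(M: InteractionMatrix, mode: str = "row_z") -> InteractionMatrix:
    """Row-scale the counts for visualization.

    ``row_prop`` divides each row by its sum; ``row_z`` standardizes each row
    to mean 0, unit variance (constant rows map to all zeros).
    """
    C = M.counts.to_numpy(dtype=float)
    if mode == "row_prop":
        sums = C.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        S = C / sums
    elif mode == "row_z":
        mu = C.mean(axis=1, keepdims=True)
        sd = C.std(axis=1, keepdims=True)
        S = np.where(sd > 0, (C - mu) / np.where(sd == 0, 1.0, sd), 0.0)
    else:
        raise ParameterError(f"unknown scaling mode '{mode}'")
    scaled = pd.DataFrame(S, index=M.counts.index, columns=M.counts.columns)
    return InteractionMatrix(
        counts=M.counts, k_neighbors=M.k_neighbors, scaled=scaled, scale_mode=mode
    )
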