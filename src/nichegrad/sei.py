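"""Spatial enrichment index and gradient summaries.

The spatial enrichment index of gene g is the spatial-weight-weighted mean
of its expression,

    SEI_g = sum_c w_c y_gc / sum_c w_c,

and its normalized form divides by the unweighted mean mu_g (plus a small
epsilon guarding division by zero),

    norm_SEI_g = SEI_g / (mu_g + eps).

Uniform weights give norm_SEI = 1 for any gene with positive mean — the
no-enrichment baseline; values above 1 mark genes whose expression
concentrates where weights are high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix
from .errors import InsufficientDataError, ParameterError
from .weights import SpatialWeights


def _aligned(expr: ExpressionMatrix, weights) -> tuple[ExpressionMatrix, np.ndarray]:
    if isinstance(weights, SpatialWeights):
        return expr.subset_cells(weights.cells), weights.values
    w = np.asarray(weights, dtype=float).ravel()
    if len(w) != len(expr.cells):
        raise ParameterError(f"{len(w)} weights vs {len(expr.cells)} cells")
    return expr, w


def compute_sei(
    expr: ExpressionMatrix, weights, epsilon: float = 1e-6
) -> pd.DataFrame:
    """Weighted-mean enrichment per gene, sorted by normalized SEI descending.

    Returns columns gene, sei, mu, norm_sei, n_cells.
    """
    expr, w = _aligned(expr, weights)
    if w.sum() <= 0:
        raise ParameterError("spatial weights sum to zero")
    Y = expr.dense()
    sei = (Y @ w) / w.sum()
    mu = Y.mean(axis=1)
    table = pd.DataFrame(
        {"gene": expr.genes, "sei": sei, "mu": mu,
         "norm_sei": sei / (mu + epsilon), "n_cells": Y.shape[1]}
    )
    return table.sort_values(
        ["norm_sei", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


@dataclass
class CorrelationResult:
    """Spearman association between one gene's expression and spatial weights."""

    rho: float
    p: float
    n_used: int
    ok: bool
    note: str = ""


def correlate_expression_weights(
    expr_gene: np.ndarray, weights, nonzero_only: bool = True
) -> CorrelationResult:
    """Spearman rank correlation of a gene's expression with spatial weights.

    With ``nonzero_only`` (the default), cells with zero expression are
    dropped before ranking. Constant expression yields a flagged
    insufficient-variation result rather than an exception.
    """
    y = np.asarray(expr_gene, dtype=float).ravel()
    w = weights.values if isinstance(weights, SpatialWeights) else np.asarray(weights, float)
    if len(y) != len(w):
        raise ParameterError(f"{len(y)} expression values vs {len(w)} weights")
    if nonzero_only:
        keep = y > 0
        y, w = y[keep], w[keep]
    if len(y) < 3:
        raise InsufficientDataError(
            f"only {len(y)} usable cells for correlation (need >= 3)"
        )
    if np.ptp(y) == 0 or np.ptp(w) == 0:
        return CorrelationResult(np.nan, np.nan, len(y), False,
                                 "insufficient variation")
    rho, p = stats.spearmanr(y, w)
    return CorrelationResult(float(rho), float(p), len(y), True)


def binned_expression(
    expr: ExpressionMatrix, weights, n_bins: int = 10
) -> pd.DataFrame:
    """Mean expression per gene across equal-width spatial-weight bins.

    Bins cover [min w, max w], right-closed with the lowest bin left-closed.
    Columns are labeled by bin midpoint; bins containing no cells are NaN.
    A single bin reduces to the overall mean per gene.
    """
    if n_bins < 1:
        raise ParameterError("n_bins must be >= 1")
    expr, w = _aligned(expr, weights)
    edges = np.linspace(w.min(), w.max(), n_bins + 1)
    mids = (edges[:-1] + edges[1:]) / 2
    # right-closed bins, lowest edge included
    idx = np.clip(np.searchsorted(edges, w, side="left") - 1, 0, n_bins - 1)
    Y = expr.dense()
    out = np.full((Y.shape[0], n_bins), np.nan)
    for b in range(n_bins):
        mask = idx == b
        if mask.any():
            out[:, b] = Y[:, mask].mean(axis=1)
    frame = pd.DataFrame(out, index=expr.genes, columns=[f"{m:.6g}" for m in mids])
    frame.index.name = "gene"
    return frame
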