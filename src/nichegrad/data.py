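"""Core data containers and I/O.

The package works on two aligned structures:

* a *cell table* — a :class:`pandas.DataFrame` with columns ``cell`` (unique
  string id), ``x``, ``y`` (planar coordinates in platform units, e.g. µm) and
  ``cluster`` (opaque categorical label, numeric or string). Extra columns are
  carried through untouched so platform exports need no pre-editing.
* an :class:`ExpressionMatrix` — genes × cells normalized log-scale
  expression, dense or sparse.

Coordinates are treated as planar Euclidean; expression is assumed already
normalized/log-transformed upstream (only non-negativity is validated here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import AlignmentError, SchemaError, ValidationError

REQUIRED_COLUMNS = ("x", "y", "cell", "cluster")


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table in place and return it.

    Raises
    ------
    SchemaError
        if a required column is absent.
    ValidationError
        on duplicate/empty cell ids or non-finite coordinates.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table is missing required column '{col}'")
    if len(df) == 0:
        raise ValidationError("cell table has no rows")
    cell = df["cell"].astype(str)
    if (cell.str.len() == 0).any():
        raise ValidationError("cell table contains an empty cell id")
    dup = cell[cell.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate cell id: '{dup.iloc[0]}'")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
        raise ValidationError(f"non-finite coordinate at row {bad}")
    return df


def load_coords(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a coordinate table (CSV or TSV) into a validated cell table.

    Header must contain x, y, cell, cluster (case-insensitive); extra columns
    are preserved. ``dialect`` is inferred from the suffix when omitted.
    """
    path = Path(path)
    if dialect is None:
        dialect = "tsv" if path.suffix.lower() in (".tsv", ".txt") else "csv"
    if dialect not in ("csv", "tsv"):
        raise SchemaError(f"unknown dialect '{dialect}'")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.lower() if c.lower() in REQUIRED_COLUMNS else c for c in df.columns]
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"coordinate file {path} is missing column '{col}'")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(coerced.isna().idxmax())
            raise ValidationError(f"non-numeric {col} coordinate at row {row}")
        df[col] = coerced
    df["cell"] = df["cell"].astype(str)
    return validate_cell_table(df)


def write_coords(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as TSV with a header row."""
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Genes × cells normalized expression.

    ``values`` may be a dense ndarray or a scipy sparse matrix (CSR).
    """

    genes: pd.Index
    cells: pd.Index
    values: np.ndarray | sp.spmatrix

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes).astype(str)
        self.cells = pd.Index(self.cells).astype(str)
        ng, nc = self.values.shape
        if ng != len(self.genes) or nc != len(self.cells):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if ng == 0 or nc == 0:
            raise ValidationError("empty expression matrix")
        if self.genes.has_duplicates:
            raise ValidationError("duplicate gene ids")
        if self.cells.has_duplicates:
            raise ValidationError("duplicate cell ids in expression matrix")
        data = self.values.data if sp.issparse(self.values) else self.values
        if not np.isfinite(data).all():
            raise ValidationError("expression contains non-finite values")
        if data.size and data.min() < 0:
            raise ValidationError("expression contains negative values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def dense(self) -> np.ndarray:
        """Return the values as a dense float array."""
        if sp.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return np.asarray(self.values, dtype=float)

    def subset_cells(self, cell_ids) -> "ExpressionMatrix":
        """Column subset (and reorder) by cell id; unknown ids raise."""
        idx = self.cells.get_indexer(pd.Index(cell_ids).astype(str))
        if (idx < 0).any():
            missing = pd.Index(cell_ids).astype(str)[idx < 0][0]
            raise AlignmentError(f"cell '{missing}' not present in expression matrix")
        vals = self.values[:, idx] if not sp.issparse(self.values) else self.values.tocsc()[:, idx].tocsr()
        return ExpressionMatrix(self.genes, self.cells[idx], vals)

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense expression vector for one gene."""
        i = self.genes.get_indexer([str(gene)])[0]
        if i < 0:
            raise ValidationError(f"unknown gene '{gene}'")
        row = self.values[i]
        if sp.issparse(self.values):
            return np.asarray(self.values[[i], :].todense(), dtype=float).ravel()
        return np.asarray(row, dtype=float)


def load_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix.

    ``mtx_triplet`` expects a MatrixMarket file plus sidecar gene and cell
    name files (one name per line). ``dense_delim`` expects gene rows with a
    cell-id header, first column holding gene ids.
    """
    path = Path(path)
    if format is None:
        format = "mtx_triplet" if path.suffix.lower() == ".mtx" else "dense_delim"
    if format == "mtx_triplet":
        if genes_path is None or cells_path is None:
            raise SchemaError("mtx_triplet format requires gene and cell name files")
        try:
            mat = scipy.io.mmread(str(path))
        except Exception as exc:  # noqa: BLE001 - surface as validation failure
            raise ValidationError(f"cannot read MTX file {path}: {exc}") from exc
        genes = _read_names(genes_path)
        cells = _read_names(cells_path)
        mat = sp.csr_matrix(mat)
        ng, nc = mat.shape
        if ng != len(genes):
            raise ValidationError(
                f"MTX declares {ng} genes but {len(genes)} gene names supplied"
            )
        if nc != len(cells):
            raise ValidationError(
                f"MTX declares {nc} cells but {len(cells)} cell names supplied"
            )
        return ExpressionMatrix(pd.Index(genes), pd.Index(cells), mat)
    if format == "dense_delim":
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise ValidationError(f"empty expression matrix in {path}")
        return ExpressionMatrix(
            pd.Index(df.index), pd.Index(df.columns), df.to_numpy(dtype=float)
        )
    raise SchemaError(f"unknown expression format '{format}'")


def write_expression(expr: ExpressionMatrix, path: str | Path, sep: str = "\t") -> None:
    """Write as dense delimited text (gene rows, cell-id header)."""
    df = pd.DataFrame(expr.dense(), index=expr.genes, columns=expr.cells)
    df.index.name = "gene"
    df.to_csv(path, sep=sep)


def write_expression_mtx(expr: ExpressionMatrix, matrix_path: str | Path,
                         genes_path: str | Path, cells_path: str | Path) -> None:
    """Write as MatrixMarket triplet plus sidecar name files."""
    mat = expr.values if sp.issparse(expr.values) else sp.coo_matrix(expr.values)
    scipy.io.mmwrite(str(matrix_path), mat)
    Path(genes_path).write_text("\n".join(expr.genes) + "\n")
    Path(cells_path).write_text("\n".join(expr.cells) + "\n")


def _read_names(path: str | Path) -> list[str]:
    names = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if not names:
        raise ValidationError(f"name file {path} is empty")
    return names


def align_dataset(
    coords: pd.DataFrame, expr: ExpressionMatrix
) -> tuple[pd.DataFrame, ExpressionMatrix, tuple[int, int]]:
    """Intersect cell ids, returning both structures in identical cell order.

    Order follows the coordinate table. Returns ``(coords, expr,
    (n_dropped_coords, n_dropped_expr))``; an empty intersection raises
    :class:`AlignmentError`.
    """
    validate_cell_table(coords)
    shared = coords["cell"].astype(str).isin(set(expr.cells))
    kept = coords.loc[shared].reset_index(drop=True)
    if len(kept) == 0:
        raise AlignmentError("coordinate table and expression matrix share no cells")
    dropped_coords = int(len(coords) - len(kept))
    dropped_expr = int(len(expr.cells) - len(kept))
    return kept, expr.subset_cells(kept["cell"]), (dropped_coords, dropped_expr)
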