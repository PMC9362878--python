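"""Reading, validation and alignment of the two core input matrices.

The tool consumes (i) a cell-by-resolution-parameter matrix of integer
cluster assignments and (ii) the matching cell-by-gene normalized
expression matrix, plus optionally a cell-by-component embedding and
per-cluster annotation tables.  Everything downstream operates on the
validated containers defined here.

Conventions
-----------
* Delimited files: comma-separated by default; tab is auto-detected from a
  ``.tsv``/``.tab`` extension.  A header row is mandatory.
* Assignment labels are integers.  String labels are rejected.
* Expression is taken as already normalized (log or linear, caller's
  choice); no normalization is applied here, and negative values are an
  error.
* MatrixMarket expression is genes x cells on disk (the common exchange
  convention) and transposed on load; set ``orientation="cells_by_genes"``
  to skip the transpose.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

_log = logging.getLogger("cellflows.io")

__all__ = [
    "CellAssignmentMatrix",
    "ExpressionMatrix",
    "EmbeddingMatrix",
    "AnnotationTable",
    "read_assignments",
    "write_assignments",
    "read_expression",
    "write_expression",
    "read_embedding",
    "write_embedding",
    "read_annotations",
    "align_cells",
]


def _sep_for(path: str | os.PathLike) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    return "\t" if ext in (".tsv", ".tab") else ","


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class CellAssignmentMatrix:
    """Cells x resolutions integer cluster assignments.

    Parameters
    ----------
    cell_ids
        Ordered, unique cell identifiers (length ``n_cells``).
    resolutions
        Strictly increasing resolution-parameter grid (length ``n_res``).
    labels
        ``(n_cells, n_res)`` integer array; ``labels[i, j]`` is the cluster
        of cell *i* at resolution ``resolutions[j]``.
    resolution_names
        The original header strings for each resolution, preserved so node
        identifiers keep the user's formatting (``"0.1"`` stays ``"0.1"``).
    label_maps
        Optional per-column ``{original_label: current_label}`` maps kept
        when labels are permuted (e.g. by size-relabeling).
    """

    cell_ids: list[str]
    resolutions: np.ndarray
    labels: np.ndarray
    resolution_names: list[str] = field(default_factory=list)
    label_maps: list[dict[int, int]] | None = None

    def __post_init__(self) -> None:
        self.resolutions = np.asarray(self.resolutions, dtype=float)
        self.labels = np.asarray(self.labels)
        if not self.resolution_names:
            self.resolution_names = [_format_resolution(r) for r in self.resolutions]
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n, m = self.labels.shape
        if len(self.cell_ids) != n:
            raise ValueError(
                f"{len(self.cell_ids)} cell ids but {n} label rows"
            )
        if len(set(self.cell_ids)) != n:
            dupes = pd.Index(self.cell_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValueError(f"duplicate cell ids: {dupes[:5]}")
        if m < 2:
            raise ValueError("at least 2 resolutions are required")
        if len(self.resolutions) != m or len(self.resolution_names) != m:
            raise ValueError("resolution grid does not match label columns")
        if np.any(np.diff(self.resolutions) <= 0):
            raise ValueError("resolutions must be strictly increasing")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.labels.shape[0]

    @property
    def n_resolutions(self) -> int:
        return self.labels.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.labels[:, j]

    def reorder(self, order: np.ndarray) -> "CellAssignmentMatrix":
        return CellAssignmentMatrix(
            cell_ids=[self.cell_ids[i] for i in order],
            resolutions=self.resolutions.copy(),
            labels=self.labels[order],
            resolution_names=list(self.resolution_names),
            label_maps=self.label_maps,
        )


def _format_resolution(r: float) -> str:
    s = f"{r:.10g}"
    return s


@dataclass
class ExpressionMatrix:
    """Cells x genes non-negative normalized expression.

    ``values`` may be dense (``numpy.ndarray``) or sparse
    (``scipy.sparse.csr_matrix``); use :meth:`gene_vector` / :meth:`submatrix`
    for uniform access.
    """

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray | sp.csr_matrix

    def __post_init__(self) -> None:
        if sp.issparse(self.values):
            self.values = sp.csr_matrix(self.values)
            vmin = self.values.data.min() if self.values.nnz else 0.0
        else:
            self.values = np.asarray(self.values, dtype=float)
            vmin = self.values.min() if self.values.size else 0.0
        n, g = self.values.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell ids but {n} rows")
        if len(self.gene_ids) != g:
            raise ValueError(f"{len(self.gene_ids)} gene ids but {g} columns")
        if len(set(self.cell_ids)) != n:
            raise ValueError("duplicate cell ids in expression matrix")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene ids in expression matrix")
        if vmin < 0:
            raise ValueError("expression values must be non-negative")
        self._gene_index = {gid: i for i, gid in enumerate(self.gene_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_column(self, gene: str) -> int:
        try:
            return self._gene_index[gene]
        except KeyError:
            near = [g for g in self.gene_ids if gene.lower() in g.lower() or g.lower() in gene.lower()]
            hint = f"; near matches: {near[:5]}" if near else ""
            raise KeyError(f"unknown gene {gene!r}{hint}") from None

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense expression of one gene over all cells."""
        col = self.gene_column(gene)
        v = self.values[:, col]
        return np.asarray(v.todense()).ravel() if sp.issparse(v) else np.asarray(v).ravel()

    def submatrix(self, rows: np.ndarray, genes: list[str]) -> np.ndarray:
        """Dense ``(len(rows), len(genes))`` block."""
        cols = [self.gene_column(g) for g in genes]
        block = self.values[np.asarray(rows)][:, cols]
        return np.asarray(block.todense()) if sp.issparse(block) else np.asarray(block)

    def reorder(self, order: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(
            cell_ids=[self.cell_ids[i] for i in order],
            gene_ids=list(self.gene_ids),
            values=self.values[np.asarray(order)],
        )


@dataclass
class EmbeddingMatrix:
    """Cells x components real coordinates (PCA scores or similar)."""

    cell_ids: list[str]
    components: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2 or self.components.shape[1] < 2:
            raise ValueError("embedding must be cells x d with d >= 2")
        if len(self.cell_ids) != self.components.shape[0]:
            raise ValueError("cell ids do not match embedding rows")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("embedding contains non-finite values")

    @property
    def n_cells(self) -> int:
        return self.components.shape[0]

    def reorder(self, order: np.ndarray) -> "EmbeddingMatrix":
        return EmbeddingMatrix(
            cell_ids=[self.cell_ids[i] for i in order],
            components=self.components[np.asarray(order)],
        )


@dataclass
class AnnotationTable:
    """Per-cluster annotations keyed by (resolution name, cluster label).

    ``table`` columns: ``resolution`` (string, matching the assignment
    matrix's resolution names), ``cluster`` (integer label), then arbitrary
    named numeric or text columns.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"resolution", "cluster"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation table missing columns: {sorted(missing)}")
        for col in self.table.columns:
            if col in required:
                continue
            series = self.table[col]
            if pd.api.types.is_numeric_dtype(series) and not np.all(np.isfinite(series.dropna())):
                raise ValueError(f"annotation column {col!r} has non-finite values")

    @property
    def value_columns(self) -> list[str]:
        return [c for c in self.table.columns if c not in ("resolution", "cluster")]

    def rows(self):
        for _, row in self.table.iterrows():
            yield str(row["resolution"]), int(row["cluster"]), {
                c: row[c] for c in self.value_columns
            }


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_assignments(path: str | os.PathLike, sep: str | None = None) -> CellAssignmentMatrix:
    """Read a cell-by-resolution assignment matrix from delimited text.

    First column holds cell ids; remaining column headers must parse as
    real resolution values.  Columns are sorted by ascending resolution;
    the original header strings are preserved for node naming.
    """
    sep = sep or _sep_for(path)
    df = pd.read_csv(path, sep=sep, header=0, dtype=str)
    if df.shape[1] < 3:
        raise ValueError("need a cell-id column plus at least 2 resolution columns")
    cell_col = df.columns[0]
    res_names = list(df.columns[1:])
    try:
        res_values = np.array([float(r) for r in res_names])
    except ValueError as e:
        raise ValueError(f"non-numeric resolution header: {e}") from None

    cell_ids = df[cell_col].astype(str).tolist()
    labels = np.empty((len(df), len(res_names)), dtype=np.int64)
    for j, name in enumerate(res_names):
        col = df[name]
        bad = col.isna() | (col.astype(str).str.strip() == "")
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"missing label for cell {cell_ids[i]!r} in resolution column {name!r}"
            )
        try:
            numeric = col.astype(float)
        except ValueError:
            raise ValueError(f"non-integer label in resolution column {name!r}") from None
        if np.any(numeric != np.floor(numeric)):
            raise ValueError(f"non-integer label in resolution column {name!r}")
        labels[:, j] = numeric.astype(np.int64)

    order = np.argsort(res_values, kind="stable")
    return CellAssignmentMatrix(
        cell_ids=cell_ids,
        resolutions=res_values[order],
        labels=labels[:, order],
        resolution_names=[res_names[j] for j in order],
    )


def write_assignments(assign: CellAssignmentMatrix, path: str | os.PathLike, sep: str | None = None) -> None:
    sep = sep or _sep_for(path)
    df = pd.DataFrame(assign.labels, columns=assign.resolution_names)
    df.insert(0, "cell_id", assign.cell_ids)
    df.to_csv(path, sep=sep, index=False)


def read_expression(
    path: str | os.PathLike,
    rows_path: str | os.PathLike | None = None,
    cols_path: str | os.PathLike | None = None,
    orientation: str = "genes_by_cells",
) -> ExpressionMatrix:
    """Read expression from delimited text or a MatrixMarket triplet.

    For ``.mtx`` input, ``rows_path``/``cols_path`` are one-id-per-line
    sidecar files naming the on-disk rows and columns.  On-disk orientation
    defaults to genes x cells and is transposed to the internal cells x
    genes layout; pass ``orientation="cells_by_genes"`` if the file is
    already cell-major.
    """
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".mtx":
        if rows_path is None or cols_path is None:
            raise ValueError("MTX input requires row and column sidecar files")
        mat = sp.csr_matrix(scipy.io.mmread(str(path)))
        row_ids = _read_id_list(rows_path)
        col_ids = _read_id_list(cols_path)
        if mat.shape != (len(row_ids), len(col_ids)):
            raise ValueError(
                f"MTX shape {mat.shape} does not match sidecars "
                f"({len(row_ids)} rows, {len(col_ids)} cols)"
            )
        if orientation == "genes_by_cells":
            return ExpressionMatrix(cell_ids=col_ids, gene_ids=row_ids, values=sp.csr_matrix(mat.T))
        elif orientation == "cells_by_genes":
            return ExpressionMatrix(cell_ids=row_ids, gene_ids=col_ids, values=mat)
        raise ValueError(f"unknown orientation {orientation!r}")

    # delimited text defaults to cells x genes (header row = genes);
    # orientation="transpose" flips a genes x cells table on load
    df = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    if orientation == "transpose":
        df = df.T
    return ExpressionMatrix(
        cell_ids=[str(i) for i in df.index],
        gene_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
    )


def _read_id_list(path: str | os.PathLike) -> list[str]:
    with open(path) as fh:
        return [line.strip().split("\t")[0] for line in fh if line.strip()]


def write_expression(
    expr: ExpressionMatrix,
    path: str | os.PathLike,
    rows_path: str | os.PathLike | None = None,
    cols_path: str | os.PathLike | None = None,
) -> None:
    """Write expression as CSV/TSV (cells x genes) or MTX (genes x cells)."""
    ext = os.path.splitext(str(path))[1].lower()
    if ext == ".mtx":
        if rows_path is None or cols_path is None:
            raise ValueError("MTX output requires row and column sidecar paths")
        mat = expr.values.T if sp.issparse(expr.values) else sp.csr_matrix(expr.values.T)
        scipy.io.mmwrite(str(path), sp.coo_matrix(mat))
        with open(rows_path, "w") as fh:
            fh.write("\n".join(expr.gene_ids) + "\n")
        with open(cols_path, "w") as fh:
            fh.write("\n".join(expr.cell_ids) + "\n")
        return
    dense = expr.values
    if sp.issparse(dense):
        dense = np.asarray(dense.todense())
    df = pd.DataFrame(dense, index=expr.cell_ids, columns=expr.gene_ids)
    df.index.name = "cell_id"
    df.to_csv(path, sep=_sep_for(path))


def read_embedding(path: str | os.PathLike) -> EmbeddingMatrix:
    df = pd.read_csv(path, sep=_sep_for(path), header=0, index_col=0)
    return EmbeddingMatrix(
        cell_ids=[str(i) for i in df.index],
        components=df.to_numpy(dtype=float),
    )


def write_embedding(emb: EmbeddingMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        emb.components,
        index=emb.cell_ids,
        columns=[f"PC{i + 1}" for i in range(emb.components.shape[1])],
    )
    df.index.name = "cell_id"
    df.to_csv(path, sep=_sep_for(path))


def read_annotations(path: str | os.PathLike) -> AnnotationTable:
    df = pd.read_csv(path, sep=_sep_for(path), header=0, dtype={"resolution": str})
    return AnnotationTable(table=df)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------


def align_cells(
    assign: CellAssignmentMatrix,
    expr: ExpressionMatrix,
    emb: EmbeddingMatrix | None = None,
    strict: bool = True,
) -> tuple[CellAssignmentMatrix, ExpressionMatrix, EmbeddingMatrix | None]:
    """Reorder all structures to one canonical cell order.

    The canonical order is the assignment matrix's order restricted to the
    shared cells.  In strict mode any mismatch between the id sets is an
    error; in permissive mode cells absent from any structure are dropped
    (the count is logged).
    """
    sets = [set(assign.cell_ids), set(expr.cell_ids)]
    if emb is not None:
        sets.append(set(emb.cell_ids))
    common = set.intersection(*sets)
    if not common:
        raise ValueError("no cells shared between the input structures")
    union = set.union(*sets)
    if strict and common != union:
        extra = sorted(union - common)
        raise ValueError(
            f"cell id sets differ ({len(extra)} unshared, e.g. {extra[:5]}); "
            "use permissive mode to drop them"
        )
    if common != union:
        _log.info("align_cells: dropping %d cells absent from some input", len(union - common))

    canonical = [c for c in assign.cell_ids if c in common]
    order_of = {c: i for i, c in enumerate(canonical)}

    def order_for(ids: list[str]) -> np.ndarray:
        pairs = [(order_of[c], i) for i, c in enumerate(ids) if c in common]
        pairs.sort()
        return np.array([i for _, i in pairs], dtype=np.intp)

    assign2 = assign.reorder(order_for(assign.cell_ids))
    expr2 = expr.reorder(order_for(expr.cell_ids))
    emb2 = emb.reorder(order_for(emb.cell_ids)) if emb is not None else None
    return assign2, expr2, emb2
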