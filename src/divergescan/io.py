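"""Data model and readers/writers for expression matrices, coordinates and results.

The package works on three external artifacts:

* a gene x cell expression matrix, either a Matrix Market triplet file with
  companion gene/cell label files, or a dense delimited table;
* a cell coordinate table (first column cell id, remaining columns numeric
  dimensions of the input space: PCs, t-SNE/UMAP, or physical coordinates);
* a per-gene result table with the divergence statistic and log10 p-values.

Log10 p-values (not raw p) are serialized throughout: extreme genes routinely
reach p < 1e-300 and would underflow a raw-p column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger("divergescan")

RESULT_COLUMNS = ["gene", "d_kl", "n_detected", "log10_pval", "log10_pval_adj", "rank"]


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of non-negative expression values.

    ``values`` may hold raw counts or normalized expression; the method only
    requires non-negativity because it binarizes downstream.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise FormatError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if np.any(self.values < 0):
            raise FormatError("expression values must be non-negative")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise FormatError(f"duplicate {name} ids in expression matrix")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class EmbeddingCoordinates:
    """Cell coordinates in the input space (>= 2 dimensions)."""

    cell_ids: np.ndarray
    coords: np.ndarray
    space_label: str = ""

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] != len(self.cell_ids):
            raise FormatError("coordinate matrix must be n_cells x n_dims")
        if self.coords.shape[1] < 2:
            raise FormatError("at least 2 dimensions required")
        if not np.all(np.isfinite(self.coords)):
            raise FormatError("coordinates must be finite")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell ids in coordinates")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def _read_labels(path: Path) -> list[str]:
    labels = [ln.strip().split("\t")[0] for ln in open(path) if ln.strip()]
    if len(set(labels)) != len(labels):
        raise FormatError(f"duplicate labels in {path}")
    return labels


def read_expression(
    path: str | Path,
    format: str | None = None,
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
    cells_as_rows: bool = False,
) -> ExpressionMatrix:
    """Read an expression matrix from disk.

    Parameters
    ----------
    path
        Matrix Market file (``format="mtx-triplet"``) or a dense delimited
        table (``format="dense-delimited"``) with a header row of cell ids and
        a first column of gene ids. When ``format`` is None it is inferred
        from the file suffix (``.mtx`` -> triplet, otherwise dense).
    genes_path, cells_path
        Label files for the mtx triplet; default to ``<stem>.genes.txt`` and
        ``<stem>.cells.txt`` beside the matrix. One label per line.
    cells_as_rows
        Transpose an mtx whose rows are cells rather than genes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "mtx-triplet" if path.suffix == ".mtx" else "dense-delimited"

    if format == "mtx-triplet":
        genes_path = Path(genes_path) if genes_path else path.with_suffix(".genes.txt")
        cells_path = Path(cells_path) if cells_path else path.with_suffix(".cells.txt")
        for p in (genes_path, cells_path):
            if not p.exists():
                raise FormatError(f"companion label file missing: {p}")
        try:
            raw = mmread(path)
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"malformed Matrix Market file {path}: {exc}") from exc
        mat = np.asarray(raw.todense()) if hasattr(raw, "todense") else np.asarray(raw)
        if cells_as_rows:
            mat = mat.T
        genes = _read_labels(genes_path)
        cells = _read_labels(cells_path)
        if mat.shape[0] != len(genes):
            raise FormatError(
                f"{genes_path}: {len(genes)} labels but matrix declares {mat.shape[0]} genes"
            )
        if mat.shape[1] != len(cells):
            raise FormatError(
                f"{cells_path}: {len(cells)} labels but matrix declares {mat.shape[1]} cells"
            )
        return ExpressionMatrix(genes, cells, mat)

    if format == "dense-delimited":
        sep = _detect_delimiter(path)
        df = pd.read_csv(path, sep=sep, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"non-numeric entry in {path}: {exc}") from exc
        return ExpressionMatrix(df.index.to_numpy(object), df.columns.to_numpy(object), values)

    raise ValueError(f"unknown format {format!r}")


def read_coordinates(path: str | Path, space_label: str = "") -> EmbeddingCoordinates:
    """Read a coordinate table: first column cell id, the rest numeric dims."""
    path = Path(path)
    sep = _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 2:
        raise FormatError("at least 2 dimensions required")
    try:
        coords = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric coordinate in {path}: {exc}") from exc
    return EmbeddingCoordinates(df.index.to_numpy(object), coords, space_label or path.stem)


def align_cells(
    expr: ExpressionMatrix, emb: EmbeddingCoordinates
) -> tuple[ExpressionMatrix, EmbeddingCoordinates]:
    """Restrict both inputs to their common cells, in identical order.

    Embeddings are frequently computed on a filtered subset of cells, so a
    partial overlap drops the unmatched ids with a warning; an empty
    intersection is fatal.
    """
    expr_pos = {c: i for i, c in enumerate(expr.cell_ids)}
    common = [c for c in emb.cell_ids if c in expr_pos]
    if not common:
        raise FormatError("expression matrix and coordinates share no cell ids")
    dropped = (set(expr.cell_ids) | set(emb.cell_ids)) - set(common)
    if dropped:
        logger.warning("align_cells: dropping %d unmatched cell ids: %s",
                       len(dropped), sorted(map(str, dropped))[:10])
    emb_pos = {c: i for i, c in enumerate(emb.cell_ids)}
    ei = np.array([expr_pos[c] for c in common])
    mi = np.array([emb_pos[c] for c in common])
    expr2 = ExpressionMatrix(expr.gene_ids, np.array(common, dtype=object), expr.values[:, ei])
    emb2 = EmbeddingCoordinates(np.array(common, dtype=object), emb.coords[mi], emb.space_label)
    return expr2, emb2


def validate_results(res: pd.DataFrame) -> pd.DataFrame:
    """Check the result-table contract and return the frame sorted by rank."""
    missing = [c for c in RESULT_COLUMNS if c not in res.columns]
    if missing:
        raise FormatError(f"result table missing columns: {missing}")
    n = len(res)
    if n and sorted(res["rank"]) != list(range(1, n + 1)):
        raise FormatError("ranks must be a permutation of 1..n_genes")
    return res.sort_values("rank").reset_index(drop=True)


def write_results(res: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV, sorted by rank, >= 6 significant digits."""
    res = validate_results(res)
    out = res[RESULT_COLUMNS].copy()
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            fh.write(
                f"{row.gene}\t{row.d_kl:.8g}\t{int(row.n_detected)}\t"
                f"{row.log10_pval:.8g}\t{row.log10_pval_adj:.8g}\t{int(row.rank)}\n"
            )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t")
    return validate_results(df)
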