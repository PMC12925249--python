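"""Readers and writers for matrices, embeddings, groupings and score tables.

Supported expression inputs: a 10x-style Matrix Market triplet directory
(matrix.mtx + genes/features + barcodes), a dense delimited table (genes in
rows, cells in columns), or an AnnData .h5ad file (transposed internally to
genes-by-cells). Internal coordinates are 0-based; the 1-based MTX convention
is converted at the boundary.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError
from .matrix import ExpressionMatrix
from .scoring import ScoreTable


def _read_label_column(path, n_expected: int | None, what: str) -> list[str]:
    """One label per line; a 2+ column TSV contributes its second column."""
    labels = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            labels.append(fields[1] if len(fields) >= 2 else fields[0])
    if n_expected is not None and len(labels) != n_expected:
        raise FormatError(
            f"{what} file {path} lists {len(labels)} entries but the matrix "
            f"header declares {n_expected}"
        )
    return labels


def read_mtx_triplet(matrix_path, genes_path, barcodes_path) -> ExpressionMatrix:
    """Read a genes-by-cells matrix from MTX coordinate format plus label files."""
    try:
        m = scipy.io.mmread(os.fspath(matrix_path))
    except Exception as exc:
        raise FormatError(f"cannot read Matrix Market file {matrix_path}: {exc}") from exc
    if not sp.issparse(m):
        raise FormatError(
            f"{matrix_path} is a dense 'array'-format Matrix Market file; "
            "only coordinate (triplet) format is supported"
        )
    genes = _read_label_column(genes_path, m.shape[0], "genes")
    barcodes = _read_label_column(barcodes_path, m.shape[1], "barcodes")
    return ExpressionMatrix(gene_ids=genes, cell_ids=barcodes, values=m.tocsc())


def read_mtx_dir(directory) -> ExpressionMatrix:
    """Read a triplet directory, accepting common 10x file-name variants."""
    d = Path(directory)

    def pick(*names):
        for name in names:
            if (d / name).exists():
                return d / name
        raise FormatError(f"none of {names} found in {d}")

    return read_mtx_triplet(
        pick("matrix.mtx"),
        pick("genes.tsv", "features.tsv"),
        pick("barcodes.tsv"),
    )


def write_mtx_triplet(matrix: ExpressionMatrix, directory) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(os.fspath(d / "matrix.mtx"), matrix.values.tocoo())
    (d / "genes.tsv").write_text("\n".join(map(str, matrix.gene_ids)) + "\n")
    (d / "barcodes.tsv").write_text("\n".join(map(str, matrix.cell_ids)) + "\n")


def read_dense_table(path) -> ExpressionMatrix:
    """Read a delimited table: first row cell ids, first column gene symbols.

    The delimiter is taken from the header (tab if present, else comma). The
    header may or may not carry a corner label for the gene column. Zeros are
    stored implicitly in the resulting sparse matrix.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise FormatError(f"{path} is empty")
    sep = "\t" if "\t" in lines[0] else ","
    header = lines[0].split(sep)
    if len(lines) < 2:
        raise FormatError(f"{path} has a header but no data rows")
    first_row_len = len(lines[1].split(sep))
    if len(header) == first_row_len:
        cell_ids = header[1:]  # corner label present
    elif len(header) == first_row_len - 1:
        cell_ids = header
    else:
        raise FormatError(
            f"row 2: {first_row_len} fields do not match header of {len(header)}"
        )
    genes, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split(sep)
        if len(fields) != len(cell_ids) + 1:
            raise FormatError(
                f"row {lineno}: {len(fields)} fields, expected {len(cell_ids) + 1}"
            )
        genes.append(fields[0])
        try:
            rows.append([float(v) for v in fields[1:]])
        except ValueError as exc:
            raise FormatError(f"row {lineno}: non-numeric value ({exc})") from exc
    if len(set(genes)) != len(genes):
        dupes = sorted({g for g in genes if genes.count(g) > 1})
        raise FormatError(f"duplicate gene symbols in {path}: {dupes[:5]}")
    return ExpressionMatrix(
        gene_ids=genes, cell_ids=cell_ids, values=sp.csc_matrix(np.asarray(rows))
    )


def read_h5ad(path, layer: str | None = None) -> ExpressionMatrix:
    """Read an AnnData .h5ad file, transposing cells-by-genes to genes-by-cells."""
    import anndata

    adata = anndata.read_h5ad(os.fspath(path))
    X = adata.layers[layer] if layer is not None else adata.X
    if X is None:
        raise FormatError(f"{path}: no expression values in {'layer ' + layer if layer else 'X'}")
    values = X.T.tocsc() if sp.issparse(X) else sp.csc_matrix(np.asarray(X).T)
    return ExpressionMatrix(
        gene_ids=adata.var_names.to_numpy(dtype=object),
        cell_ids=adata.obs_names.to_numpy(dtype=object),
        values=values,
    )


def read_expression(path, layer: str | None = None) -> ExpressionMatrix:
    """Dispatch on input type: MTX directory, .h5ad file, or dense table."""
    p = Path(path)
    if p.is_dir():
        return read_mtx_dir(p)
    if p.suffix == ".h5ad":
        return read_h5ad(p, layer=layer)
    if p.suffix == ".mtx":
        raise FormatError(
            "a bare .mtx file lacks gene/barcode labels; pass its directory "
            "or use read_mtx_triplet() with explicit label paths"
        )
    return read_dense_table(p)


def read_embedding_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Delimited embedding: first column cell_id, remaining columns numeric.

    Returns (cell_ids, cells-by-components array).
    """
    sep = "\t" if "\t" in Path(path).read_text(encoding="utf-8").splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise FormatError(f"{path}: embedding has no numeric columns")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric embedding value ({exc})") from exc
    return df.index.to_numpy(dtype=object), values


def read_grouping(path) -> pd.Series:
    """Two-column TSV/CSV mapping cell_id to group label."""
    sep = "\t" if "\t" in Path(path).read_text(encoding="utf-8").splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: grouping file needs two columns (cell_id, group)")
    # tolerate a header row
    if df.iloc[0, 0] in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def write_scores(
    table: ScoreTable, path, smoothed: bool = False, float_format: str = "%.6g"
) -> None:
    """Write a score table as TSV; undefined scores become empty fields."""
    table.to_frame(smoothed=smoothed).to_csv(
        path, sep="\t", na_rep="", float_format=float_format
    )


def write_aggregates(aggregates: pd.DataFrame, path, float_format: str = "%.6g") -> None:
    aggregates.to_csv(path, sep="\t", index=False, na_rep="", float_format=float_format)
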