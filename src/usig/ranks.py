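"""Per-cell gene ranking with midrank ties and rank capping.

Genes are ranked within each cell in *descending* expression order (rank 1 =
highest expression), over the cell's full gene profile. Tied values receive
their midrank — the average of the positions they span — which is the standard
Mann-Whitney convention and makes scores invariant to the gene order of the
input file. Ranks are then capped at ``r_max`` so that the large tail of
undetected (zero) genes typical of sparse single-cell data cannot dominate
the statistic; capping is applied *after* midrank assignment, so capped ties
are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.stats import rankdata

from .errors import ParameterError


@dataclass
class CellRankVector:
    """Capped descending ranks for the queried genes of one cell."""

    cell_id: object
    ranks: dict[int, float]
    r_max: int


def base_ranks(X: np.ndarray) -> np.ndarray:
    """Uncapped descending midranks per column of a dense genes-by-cells block."""
    return rankdata(-X, method="average", axis=0)


def rank_cell(
    expression: Sequence[float],
    r_max: int,
    query_indices: Sequence[int],
    cell_id: object = None,
) -> CellRankVector:
    """Rank one cell's expression vector and return capped ranks for a query.

    Ranking is over *all* genes of the cell; only the requested indices are
    materialized in the result.
    """
    if r_max < 1:
        raise ParameterError(f"r_max must be >= 1, got {r_max}")
    expr = np.asarray(expression, dtype=float)
    if expr.ndim != 1:
        raise ParameterError("expression must be a 1-D vector")
    query = np.asarray(query_indices, dtype=int)
    if query.size and (query.min() < 0 or query.max() >= expr.size):
        raise IndexError(
            f"query index out of bounds for a cell with {expr.size} genes"
        )
    ranks = np.minimum(rankdata(-expr, method="average"), float(r_max))
    return CellRankVector(
        cell_id=cell_id,
        ranks={int(i): float(ranks[i]) for i in query},
        r_max=int(r_max),
    )


def rank_chunk(
    chunk,
    r_max: int,
    query_indices: Sequence[int],
    cell_ids: Sequence[object] | None = None,
) -> list[CellRankVector]:
    """Rank every cell (column) of a genes-by-cells chunk.

    Accepts a dense array or any scipy sparse matrix; output is elementwise
    identical to calling :func:`rank_cell` per column, in column order.
    """
    if r_max < 1:
        raise ParameterError(f"r_max must be >= 1, got {r_max}")
    X = chunk.toarray() if sp.issparse(chunk) else np.asarray(chunk, dtype=float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ParameterError("chunk must be a genes-by-cells matrix with >= 1 cell")
    query = np.asarray(query_indices, dtype=int)
    if query.size and (query.min() < 0 or query.max() >= X.shape[0]):
        raise IndexError(
            f"query index out of bounds for a chunk with {X.shape[0]} genes"
        )
    capped = np.minimum(base_ranks(X), float(r_max))
    out = []
    for j in range(X.shape[1]):
        cid = cell_ids[j] if cell_ids is not None else j
        out.append(
            CellRankVector(
                cell_id=cid,
                ranks={int(i): float(capped[i, j]) for i in query},
                r_max=int(r_max),
            )
        )
    return out
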