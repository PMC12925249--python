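"""Decay-weighted kNN smoothing of per-cell signature scores.

Sparse single-cell data makes per-cell scores noisy: a cell may score zero
simply because its signature genes dropped out. Smoothing replaces each
cell's score with a weighted average over the ordered sequence
[self, neighbor_1, ..., neighbor_k] of its k nearest neighbors in an
embedding (typically PCA) space, with weight (1 - lambda)^i for the i-th
element. The cell itself sits at i = 0 with weight 1, which reproduces the
two stated limits exactly: lambda = 1 leaves scores untouched (all neighbor
weights vanish) and lambda = 0 takes the unweighted mean of self plus
neighbors. Smoothing acts only on score tables — the expression matrix is
never modified, in contrast to gene-level imputation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA

from .errors import DegenerateEmbeddingError, ParameterError
from .matrix import ExpressionMatrix
from .scoring import ScoreTable


@dataclass
class SmoothingParams:
    """k: neighbor count; decay: lambda in [0, 1]; n_components/target_sum
    control the internally computed PCA embedding when none is supplied."""

    k: int = 10
    decay: float = 0.1
    n_components: int = 20
    target_sum: float = 10_000.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.decay <= 1.0:
            raise ParameterError(f"decay (lambda) must be in [0, 1], got {self.decay}")
        if self.n_components < 1:
            raise ParameterError(f"n_components must be >= 1, got {self.n_components}")


@dataclass
class NeighborGraph:
    """Per-cell ordered neighbor indices (ascending distance) and distances.

    Neighbor lists exclude the cell itself and hold min(k, n_cells - 1)
    entries each; ties in distance are broken by ascending cell index.
    """

    indices: np.ndarray
    distances: np.ndarray

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.indices.shape != self.distances.shape or self.indices.ndim != 2:
            raise ParameterError("indices and distances must be matching 2-D arrays")

    @property
    def n_cells(self) -> int:
        return self.indices.shape[0]

    @property
    def k(self) -> int:
        return self.indices.shape[1]


def compute_embedding(
    matrix: ExpressionMatrix,
    n_components: int = 20,
    seed: int = 0,
    target_sum: float = 10_000.0,
) -> np.ndarray:
    """Standard normalize/log1p/PCA embedding of cells.

    Each cell is scaled to ``target_sum`` total counts, log1p-transformed,
    and genes are centered before a full (deterministic) truncated PCA. The
    sign of each component is fixed so that its largest-magnitude gene
    loading is positive, making the embedding reproducible across runs.
    """
    if n_components < 1 or n_components > min(matrix.n_genes, matrix.n_cells):
        raise ParameterError(
            f"n_components must be in [1, {min(matrix.n_genes, matrix.n_cells)}], "
            f"got {n_components}"
        )
    X = np.asarray(matrix.values.T.todense(), dtype=float)  # cells x genes
    totals = X.sum(axis=1)
    scale = np.divide(target_sum, totals, out=np.zeros_like(totals), where=totals > 0)
    Xn = np.log1p(X * scale[:, None])
    if not np.any(Xn.var(axis=0) > 0):
        raise DegenerateEmbeddingError(
            "matrix has no gene with variance across cells; embedding is degenerate"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    Y = pca.fit_transform(Xn)
    # deterministic sign convention on each component
    for c in range(n_components):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            Y[:, c] = -Y[:, c]
    return Y


def find_knn(embedding: np.ndarray, k: int) -> NeighborGraph:
    """Exact Euclidean k nearest neighbors, self excluded.

    Deterministic: equal distances are resolved toward the lower cell index.
    k is truncated to n_cells - 1 (with a warning) when too large; a
    single-cell input yields an empty graph.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    E = np.asarray(embedding, dtype=float)
    if E.ndim != 2:
        raise ParameterError("embedding must be a cells-by-components 2-D array")
    n = E.shape[0]
    if n == 1:
        warnings.warn("single cell: neighbor graph is empty", UserWarning, stacklevel=2)
        return NeighborGraph(np.empty((1, 0), dtype=int), np.empty((1, 0)))
    if k >= n:
        warnings.warn(
            f"k={k} >= n_cells={n}; truncating to {n - 1}", UserWarning, stacklevel=2
        )
        k = n - 1
    D = cdist(E, E, metric="euclidean")
    np.fill_diagonal(D, np.inf)
    # stable argsort on distances resolves ties toward the lower column index
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    dist = np.take_along_axis(D, order, axis=1)
    return NeighborGraph(order, dist)


def smooth_scores(table: ScoreTable, graph: NeighborGraph, decay: float) -> ScoreTable:
    """Smooth a score table over a neighbor graph with decay parameter lambda.

    Returns a new table carrying both the original scores and the smoothed
    ones (``.smoothed``). Undefined (NaN) contributions are dropped from
    numerator and denominator; a cell whose every contributor is undefined
    stays undefined.
    """
    if not 0.0 <= decay <= 1.0:
        raise ParameterError(f"decay (lambda) must be in [0, 1], got {decay}")
    n, _ = table.scores.shape
    if graph.n_cells != n:
        raise ParameterError(
            f"neighbor graph covers {graph.n_cells} cells but table has {n}"
        )
    k = graph.k
    self_idx = np.arange(n)[:, None]
    seq = np.hstack([self_idx, graph.indices])  # n x (k+1), self first
    vals = table.scores[seq, :]  # n x (k+1) x sigs
    w = (1.0 - decay) ** np.arange(k + 1)  # (1-lambda)^0 = 1 even at lambda=1
    defined = ~np.isnan(vals)
    wts = w[None, :, None] * defined
    num = (np.where(defined, vals, 0.0) * wts).sum(axis=1)
    den = wts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    smoothed = np.where(np.isnan(smoothed), np.nan, np.clip(smoothed, 0.0, 1.0))
    return ScoreTable(
        cell_ids=table.cell_ids,
        signature_names=list(table.signature_names),
        scores=table.scores.copy(),
        smoothed=smoothed,
    )
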