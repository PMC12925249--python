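"""Mann-Whitney U signature scores per cell, with chunked evaluation.

For a cell *j* and a gene set of effective size *n*, let r_1..r_n be the
descending midranks of the set's genes within the cell's full expression
profile, capped at ``r_max``. The score is

    score = 1 - U / U_max,         U = sum_i r_i - n(n+1)/2,
    U_max = n * r_max - n(n+1)/2,

so a set occupying the top n ranks scores 1 and a fully capped (undetected)
set scores 0. The legacy normalization ``U_max = n * r_max`` of the first
release of this statistic overestimated the theoretical maximum of U and is
kept only behind the ``legacy_norm`` flag for comparison; it yields scores
greater than or equal to the corrected ones.

Signatures with positive and negative sets are scored as two components and
combined as ``max(0, score_pos - w * score_neg)``, clipped into [0, 1].

Missing genes under the ``impute_zero`` policy are scored exactly as if one
all-zero row per missing gene had been appended to the matrix: ranks of
measured genes shift accordingly (by m for values below zero, by m/2 for
zero ties) and each imputed gene takes the zero-tail midrank of the augmented
column, all before capping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .errors import (
    ParameterError,
    UndefinedStatisticError,
    UnscorableSignatureWarning,
    MissingGenesWarning,
)
from .matrix import ExpressionMatrix
from .ranks import base_ranks
from .signatures import GeneSignature, ResolvedSignature, resolve_signature

SCORE_SUFFIX = "_UCell"
SMOOTHED_SUFFIX = "_UCell_kNN"


@dataclass
class ScoringParams:
    """Tunable parameters of the scoring run.

    r_max : rank cap; should approximate the median number of detected genes
        per cell. The default 1500 suits 10x Chromium scRNA-seq; lower it for
        targeted panels (spatial probe panels, ADT) with small feature spaces.
    neg_weight : weight w of the negative component in the combined score.
    policy : missing-gene policy, ``impute_zero`` or ``skip``.
    chunk_size : cells per mini-batch; results are independent of it.
    legacy_norm : use the historical U_max = n * r_max normalization.
    """

    r_max: int = 1500
    neg_weight: float = 1.0
    policy: str = "impute_zero"
    chunk_size: int = 500
    legacy_norm: bool = False

    def __post_init__(self) -> None:
        if self.r_max < 1:
            raise ParameterError(f"r_max must be >= 1, got {self.r_max}")
        if self.neg_weight < 0:
            raise ParameterError(f"neg_weight must be >= 0, got {self.neg_weight}")
        if self.chunk_size < 1:
            raise ParameterError(f"chunk_size must be >= 1, got {self.chunk_size}")


@dataclass
class ScoreTable:
    """Cells-by-signatures score matrix; NaN marks undefined (unscorable) entries."""

    cell_ids: np.ndarray
    signature_names: list[str]
    scores: np.ndarray
    smoothed: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.cell_ids), len(self.signature_names)):
            raise ParameterError("score matrix shape does not match labels")

    @property
    def undefined_mask(self) -> np.ndarray:
        return np.isnan(self.scores)

    def to_frame(self, smoothed: bool = False) -> pd.DataFrame:
        """Scores as a DataFrame indexed by cell_id with suffixed columns."""
        if smoothed:
            if self.smoothed is None:
                raise ParameterError("no smoothed scores present in this table")
            data, suffix = self.smoothed, SMOOTHED_SUFFIX
        else:
            data, suffix = self.scores, SCORE_SUFFIX
        return pd.DataFrame(
            data,
            index=pd.Index(self.cell_ids, name="cell_id"),
            columns=[name + suffix for name in self.signature_names],
        )


def u_statistic(ranks: Sequence[float], n: int) -> float:
    """Mann-Whitney U from capped descending ranks: sum(r) - n(n+1)/2."""
    if n == 0:
        raise UndefinedStatisticError("U statistic undefined for an empty gene set")
    if n < 0 or len(ranks) != n:
        raise ParameterError(f"expected {n} ranks, got {len(ranks)}")
    return float(np.sum(ranks) - n * (n + 1) / 2.0)


def _u_max(n: int, r_max: int, legacy_norm: bool) -> float:
    return float(n * r_max) if legacy_norm else float(n * r_max - n * (n + 1) / 2.0)


def ucell_component(
    ranks: Sequence[float], n: int, r_max: int, legacy_norm: bool = False
) -> float:
    """Score of one gene set: 1 - U/U_max, clamped to [0, 1].

    NaN (undefined) when r_max < n or U_max <= 0; e.g. a signature larger
    than the rank cap has no meaningful maximum statistic.
    """
    u = u_statistic(ranks, n)
    if r_max < n:
        return float("nan")
    umax = _u_max(n, r_max, legacy_norm)
    if umax <= 0:
        return float("nan")
    return float(min(1.0, max(0.0, 1.0 - u / umax)))


def combine_pos_neg(score_pos: float, score_neg: float | None, w: float = 1.0) -> float:
    """Combined score max(0, pos - w*neg); the positive score when neg is absent."""
    if w < 0:
        raise ParameterError(f"neg_weight must be >= 0, got {w}")
    if score_neg is None:
        return float(score_pos)
    return float(min(1.0, max(0.0, score_pos - w * score_neg)))


def _set_scores(
    base: np.ndarray,
    X: np.ndarray,
    indices: Sequence[int],
    n_missing_set: int,
    n_missing_total: int,
    params: ScoringParams,
    pos_count: np.ndarray,
    zero_count: np.ndarray,
) -> np.ndarray | None:
    """Vectorized component scores for one gene set over a chunk of cells.

    Under ``impute_zero`` the whole signature's missing genes (both sets)
    are conceptually appended as all-zero rows of one augmented matrix, so
    rank shifts use the signature-wide count ``n_missing_total`` while the
    effective set size grows only by ``n_missing_set``.

    Returns a (cells,) array, or None if the effective set is empty.
    """
    idx = np.asarray(indices, dtype=int)
    impute = params.policy == "impute_zero"
    m_set = n_missing_set if impute else 0
    m_tot = n_missing_total if impute else 0
    n = idx.size + m_set
    if n == 0:
        return None
    c = X.shape[1]
    r_max = float(params.r_max)
    umax = _u_max(n, params.r_max, params.legacy_norm)
    if params.r_max < n or umax <= 0:
        return np.full(c, np.nan)
    R = base[idx, :]
    if m_tot > 0:
        V = X[idx, :]
        # rank shifts induced by appending m_tot all-zero rows
        R = R + m_tot * (V < 0) + (m_tot / 2.0) * (V == 0)
        imputed = pos_count + (zero_count + m_tot + 1) / 2.0
        total = np.minimum(R, r_max).sum(axis=0) + m_set * np.minimum(imputed, r_max)
    else:
        total = np.minimum(R, r_max).sum(axis=0)
    u = total - n * (n + 1) / 2.0
    return np.clip(1.0 - u / umax, 0.0, 1.0)


def _score_chunk(
    X: np.ndarray, resolved: Sequence[ResolvedSignature], params: ScoringParams
) -> np.ndarray:
    """Score all signatures on one dense genes-by-cells block."""
    base = base_ranks(X)
    pos_count = (X > 0).sum(axis=0).astype(float)
    zero_count = (X == 0).sum(axis=0).astype(float)
    out = np.full((X.shape[1], len(resolved)), np.nan)
    for j, rs in enumerate(resolved):
        m_tot = rs.n_missing
        s_pos = _set_scores(
            base, X, rs.pos_indices, len(rs.pos_missing), m_tot, params,
            pos_count, zero_count,
        )
        if s_pos is None:
            continue  # positive set empty: undefined
        if rs.signature.negative:
            s_neg = _set_scores(
                base, X, rs.neg_indices, len(rs.neg_missing), m_tot, params,
                pos_count, zero_count,
            )
            if s_neg is None:
                combined = s_pos  # negative set vanished under skip: treat as absent
            else:
                combined = np.clip(s_pos - params.neg_weight * s_neg, 0.0, 1.0)
        else:
            combined = s_pos
        out[:, j] = combined
    return out


def score_signatures(
    matrix: ExpressionMatrix,
    signatures: Sequence[GeneSignature],
    params: ScoringParams | None = None,
    n_jobs: int = 1,
) -> ScoreTable:
    """Score every signature for every cell of the matrix.

    Cells are processed in mini-batches of ``params.chunk_size`` columns;
    the per-cell full-profile rank vector is computed once per chunk and
    shared across signatures. The result is identical for any chunk size and
    any ``n_jobs``. Unscorable entries (empty positive set after resolution,
    or r_max smaller than the effective set size) are NaN, never 0.
    """
    if params is None:
        params = ScoringParams()
    if matrix.n_cells < 1 or matrix.n_genes < 1:
        raise ParameterError("matrix must have at least one gene and one cell")
    if not signatures:
        raise ParameterError("no signatures to score")

    resolved = [resolve_signature(s, matrix.gene_ids, params.policy) for s in signatures]
    for rs in resolved:
        if rs.n_missing:
            warnings.warn(
                f"signature {rs.signature.name!r}: {rs.n_missing} gene(s) not in "
                f"the matrix ({params.policy} policy): "
                f"{list(rs.pos_missing + rs.neg_missing)[:10]}",
                MissingGenesWarning,
                stacklevel=2,
            )
        pos_gone = rs.signature.positive and rs.n_pos == 0
        if not rs.is_scorable or pos_gone or not rs.signature.positive:
            warnings.warn(
                f"signature {rs.signature.name!r} has no scorable positive gene "
                "set; its scores are reported as undefined",
                UnscorableSignatureWarning,
                stacklevel=2,
            )

    bounds = list(range(0, matrix.n_cells, params.chunk_size))
    blocks = Parallel(n_jobs=n_jobs, prefer="threads")(
        delayed(_score_chunk)(
            matrix.dense_block(start, min(start + params.chunk_size, matrix.n_cells)),
            resolved,
            params,
        )
        for start in bounds
    )
    scores = np.vstack(blocks)
    return ScoreTable(
        cell_ids=matrix.cell_ids,
        signature_names=[s.name for s in signatures],
        scores=scores,
    )


def aggregate_scores(
    table: ScoreTable, grouping: Mapping[object, object] | pd.Series
) -> pd.DataFrame:
    """Per-group mean scores, the recommended unit for between-sample tests.

    Treating single cells as replicates inflates significance
    (pseudo-replication); averaging scores per sample/group first restores
    the sample as the experimental unit. Undefined (NaN) cell scores are
    excluded from the mean; a group with no defined score for a signature
    gets a NaN aggregate.

    Returns a long-form DataFrame with columns
    ``group, signature, mean_score, n_defined, n_cells``.
    """
    labels = pd.Series(grouping)
    missing = [c for c in table.cell_ids if c not in labels.index]
    if missing:
        raise ParameterError(
            f"{len(missing)} cell(s) have no group label, e.g. {missing[:5]}"
        )
    labels = labels.reindex(table.cell_ids)
    rows = []
    for group in pd.unique(labels.values):
        sel = (labels.values == group)
        block = table.scores[sel, :]
        for j, name in enumerate(table.signature_names):
            col = block[:, j]
            defined = ~np.isnan(col)
            rows.append(
                {
                    "group": group,
                    "signature": name,
                    "mean_score": float(col[defined].mean()) if defined.any() else np.nan,
                    "n_defined": int(defined.sum()),
                    "n_cells": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows, columns=["group", "signature", "mean_score", "n_defined", "n_cells"])
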