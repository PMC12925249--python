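from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from usig import ExpressionMatrix, GeneSignature, parse_signature

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_matrix(rng: np.random.Generator, n_genes: int, n_cells: int,
                sparsity: float = 0.7, lam: float = 2.0) -> ExpressionMatrix:
    """Random sparse count matrix with approximately the requested zero fraction."""
    X = rng.poisson(lam, (n_genes, n_cells)).astype(float)
    X *= rng.random((n_genes, n_cells)) > sparsity
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{j}" for j in range(n_cells)],
        values=X,
    )


def random_signature(
    rng: np.random.Generator,
    genes: list[str],
    n_pos_max: int = 5,
    n_neg_max: int = 3,
    extra_missing: int = 0,
    name: str = "sig",
) -> GeneSignature:
    pool = list(genes) + [f"missing{i}" for i in range(extra_missing)]
    n_pos = int(rng.integers(1, n_pos_max + 1))
    n_neg = int(rng.integers(0, n_neg_max + 1))
    chosen = list(rng.choice(pool, size=min(n_pos + n_neg, len(pool)), replace=False))
    tokens = [t + "+" for t in chosen[:n_pos]] + [t + "-" for t in chosen[n_pos:]]
    return parse_signature(name, tokens)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260925)


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """4 genes x 1 cell, expression [5, 3, 0, 0] — the hand-checked example."""
    return ExpressionMatrix(
        gene_ids=["g1", "g2", "g3", "g4"],
        cell_ids=["c1"],
        values=np.array([[5.0], [3.0], [0.0], [0.0]]),
    )
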