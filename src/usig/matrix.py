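"""The genes-by-cells expression matrix container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .errors import FormatError


@dataclass
class ExpressionMatrix:
    """Sparse genes-by-cells matrix with gene and cell identifiers.

    ``values`` is stored as CSC for cheap column (cell) slicing. Explicitly
    stored zeros and absent entries are equivalent for scoring; readers call
    ``eliminate_zeros`` so the distinction never survives I/O. Values may be
    raw counts or normalized expression — scoring is rank-based and never
    normalizes internally.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: sp.csc_matrix

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csc_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsc().astype(float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene labels x {len(self.cell_ids)} cell labels"
            )
        for name, labels in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(labels)) != len(labels):
                raise FormatError(f"duplicate {name} identifiers in matrix labels")
        self.values.eliminate_zeros()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def sparsity(self) -> float:
        """Fraction of zero entries."""
        total = self.n_genes * self.n_cells
        return 1.0 - self.values.nnz / total if total else 0.0

    def dense_block(self, start: int, stop: int) -> np.ndarray:
        """Densify the column slice [start, stop) as a genes-by-cells array."""
        return np.asarray(self.values[:, start:stop].todense(), dtype=float)
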