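"""Core in-memory container for raw single-cell count data.

The internal orientation is genes x cells (rows are genes), matching the
layout the rest of the pipeline assumes. AnnData's cells x genes convention
is transposed at the I/O boundary (see :mod:`rankcell.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


@dataclass
class RawDataset:
    """Sparse genes x cells raw count matrix with gene and cell metadata.

    Attributes
    ----------
    counts
        Sparse CSR matrix of shape (n_genes, n_cells), non-negative integers.
    gene_ids
        Unique gene identifiers, one per matrix row.
    mito_flags
        Boolean per gene, True for mitochondrially encoded genes.
    cell_meta
        Per-cell metadata; the index holds cell identifiers. Conventional
        columns: ``dataset_id``, ``cell_type``, ``condition``.
    """

    counts: sparse.csr_matrix
    gene_ids: np.ndarray
    mito_flags: np.ndarray
    cell_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        self.counts = sparse.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.mito_flags = np.asarray(self.mito_flags, dtype=bool)
        if self.cell_meta is None or len(self.cell_meta) == 0:
            self.cell_meta = pd.DataFrame(
                index=[f"cell{i}" for i in range(self.counts.shape[1])]
            )
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def cell_ids(self) -> np.ndarray:
        return self.cell_meta.index.to_numpy()

    def validate(self) -> None:
        if len(self.gene_ids) != self.counts.shape[0]:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {self.counts.shape[0]}"
            )
        if len(self.mito_flags) != self.counts.shape[0]:
            raise ValueError("mito_flags length mismatch")
        if len(self.cell_meta) != self.counts.shape[1]:
            raise ValueError(
                f"cell_meta length {len(self.cell_meta)} != matrix columns {self.counts.shape[1]}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dupes = pd.Series(self.gene_ids).value_counts()
            raise ValueError(
                f"gene_ids not unique: {list(dupes[dupes > 1].index[:5])}"
            )
        if self.counts.nnz:
            d = self.counts.data
            if d.min() < 0:
                raise ValueError("counts must be non-negative")
            if not np.allclose(d, np.round(d)):
                raise ValueError("counts must be integer-valued")

    # ------------------------------------------------------------------
    def subset_cells(self, index) -> "RawDataset":
        """Return a new dataset restricted to the given cell positions."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return RawDataset(
            counts=self.counts[:, index].tocsr(),
            gene_ids=self.gene_ids.copy(),
            mito_flags=self.mito_flags.copy(),
            cell_meta=self.cell_meta.iloc[index].copy(),
        )

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.gene_ids == gene_id)
        if idx.size == 0:
            raise KeyError(f"gene {gene_id!r} not in dataset")
        return int(idx[0])

    def cell_counts(self, j: int) -> np.ndarray:
        """Dense count vector (length n_genes) for cell column ``j``."""
        return np.asarray(self.counts[:, j].todense()).ravel()

    def equals(self, other: "RawDataset") -> bool:
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and np.array_equal(self.gene_ids, other.gene_ids)
            and np.array_equal(self.mito_flags, other.mito_flags)
            and self.cell_meta.equals(other.cell_meta)
        )
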