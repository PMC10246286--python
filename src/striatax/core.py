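"""Core data container shared by all pipeline stages.

The central object is :class:`CountMatrix`: a sparse cells x genes matrix of
UMI counts (or normalized expression) together with per-cell metadata
(``obs``) and per-gene annotations (``var``).  The orientation follows the
single-cell convention of rows = cells, columns = genes; on-disk MatrixMarket
files use the transposed genes x cells layout (see :mod:`striatax.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = ["CountMatrix"]

#: boolean per-gene annotation columns recognised by the QC / HVG machinery
GENE_FLAG_COLUMNS = ("mito", "ribo", "sex")


@dataclass
class CountMatrix:
    """Sparse cells x genes expression matrix with aligned metadata.

    Parameters
    ----------
    X
        ``(n_cells, n_genes)`` sparse matrix (stored as CSR).
    obs
        Per-cell metadata indexed by barcode.  The pipeline expects the
        columns ``sample`` and ``region`` to be present for compositional
        and pseudobulk operations.
    var
        Per-gene annotation indexed by gene name.  Boolean columns
        ``mito``/``ribo``/``sex`` flag the corresponding gene groups.
    """

    X: sp.csr_matrix
    obs: pd.DataFrame
    var: pd.DataFrame
    uns: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not sp.issparse(self.X):
            self.X = sp.csr_matrix(np.asarray(self.X))
        else:
            self.X = self.X.tocsr()
        if self.X.shape != (len(self.obs), len(self.var)):
            raise ValueError(
                f"matrix shape {self.X.shape} does not match obs/var sizes "
                f"({len(self.obs)}, {len(self.var)})"
            )
        if self.obs.index.has_duplicates:
            raise ValueError("duplicate cell barcodes in obs index")
        if self.var.index.has_duplicates:
            raise ValueError("duplicate gene names in var index")

    # ------------------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    @property
    def gene_names(self) -> pd.Index:
        return self.var.index

    @property
    def barcodes(self) -> pd.Index:
        return self.obs.index

    # ------------------------------------------------------------------
    def total_counts(self) -> np.ndarray:
        """Per-cell total UMI counts."""
        return np.asarray(self.X.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        """Per-cell number of genes with nonzero counts."""
        return self.X.getnnz(axis=1).astype(np.int64)

    def gene_flag(self, name: str) -> np.ndarray:
        """Boolean per-gene flag column; absent column means all-False."""
        if name in self.var.columns:
            return self.var[name].to_numpy(dtype=bool)
        return np.zeros(self.n_genes, dtype=bool)

    def flagged_genes(self) -> np.ndarray:
        """Union of the mito/ribo/sex flags."""
        mask = np.zeros(self.n_genes, dtype=bool)
        for col in GENE_FLAG_COLUMNS:
            mask |= self.gene_flag(col)
        return mask

    # ------------------------------------------------------------------
    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            X=self.X[idx],
            obs=self.obs.iloc[np.flatnonzero(idx)] if idx.dtype == bool else self.obs.iloc[idx],
            var=self.var.copy(),
            uns=dict(self.uns),
        )

    def subset_genes(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        return CountMatrix(
            X=self.X[:, idx],
            obs=self.obs.copy(),
            var=self.var.iloc[np.flatnonzero(idx)] if idx.dtype == bool else self.var.iloc[idx],
            uns=dict(self.uns),
        )

    def gene_vector(self, gene: str) -> np.ndarray:
        """Dense per-cell expression of one gene."""
        j = self.var.index.get_loc(gene)
        return np.asarray(self.X[:, j].todense()).ravel()

    def copy(self) -> "CountMatrix":
        return CountMatrix(self.X.copy(), self.obs.copy(), self.var.copy(), dict(self.uns))
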