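"""Normalization helpers shared by QC and taxonomy stages."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .core import CountMatrix

__all__ = ["normalize_log", "log_normalized_dense"]


def normalize_log(matrix: CountMatrix, target_sum: float = 10_000.0) -> CountMatrix:
    """Scale each cell to ``target_sum`` total counts, then apply log1p.

    Cells with zero total counts are left as all-zero rows.
    """
    X = matrix.X.astype(np.float64).tocsr(copy=True)
    totals = np.asarray(X.sum(axis=1)).ravel()
    scale = np.ones_like(totals)
    nz = totals > 0
    scale[nz] = target_sum / totals[nz]
    X = sp.diags(scale) @ X
    X.data = np.log1p(X.data)  # sparse-safe: log1p(0) == 0
    return CountMatrix(X=X.tocsr(), obs=matrix.obs.copy(), var=matrix.var.copy(),
                       uns=dict(matrix.uns))


def log_normalized_dense(matrix: CountMatrix, genes: list[str],
                         target_sum: float = 10_000.0) -> np.ndarray:
    """Dense cells x len(genes) block of log-normalized expression."""
    idx = [matrix.var.index.get_loc(g) for g in genes]
    X = matrix.X[:, idx].astype(np.float64).toarray()
    totals = matrix.total_counts().astype(np.float64)
    nz = totals > 0
    X[nz] *= (target_sum / totals[nz])[:, None]
    return np.log1p(X)
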