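"""Reading and writing 10x-style MTX triplets with sidecar metadata.

On disk the matrix is genes x cells (MatrixMarket integer coordinate,
1-based), accompanied by ``features.tsv``, ``barcodes.tsv`` and a
``metadata.tsv`` holding per-cell sample/region columns.  This mirrors the
layout produced by common droplet pipelines while staying plain-text.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import CountMatrix

__all__ = ["write_10x", "read_10x"]

_MATRIX = "matrix.mtx"
_FEATURES = "features.tsv"
_BARCODES = "barcodes.tsv"
_METADATA = "metadata.tsv"


def write_10x(matrix: CountMatrix, path: str | os.PathLike) -> Path:
    """Write ``matrix`` as an MTX triplet plus metadata TSV under ``path``.

    Raises ``ValueError`` on an empty matrix and ``OSError`` if the target
    is not writable.  Round-trips losslessly through :func:`read_10x`.
    """
    if matrix.n_genes == 0 or matrix.n_cells == 0:
        raise ValueError("refusing to write an empty matrix (no genes or no cells)")
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)

    # genes x cells on disk, 1-based coordinate format
    gxc = sp.coo_matrix(matrix.X.T)
    scipy.io.mmwrite(str(out / _MATRIX), gxc, field="integer")

    feats = pd.DataFrame(
        {
            "gene_id": matrix.var.index,
            "gene_name": matrix.var.index,
            "feature_type": "Gene Expression",
        }
    )
    for col in ("mito", "ribo", "sex"):
        if col in matrix.var.columns:
            feats[col] = matrix.var[col].to_numpy(dtype=bool)
    feats.to_csv(out / _FEATURES, sep="\t", header=False, index=False)

    pd.Series(matrix.obs.index).to_csv(out / _BARCODES, header=False, index=False)

    meta = matrix.obs.reset_index(names="barcode")
    meta.to_csv(out / _METADATA, sep="\t", index=False)
    return out


def read_10x(path: str | os.PathLike) -> CountMatrix:
    """Read a directory written by :func:`write_10x` (or CellRanger-like)."""
    src = Path(path)
    X = sp.csr_matrix(scipy.io.mmread(str(src / _MATRIX)).T)
    if X.dtype != np.int64:
        X = X.astype(np.int64)

    feats = pd.read_csv(src / _FEATURES, sep="\t", header=None)
    gene_names = feats.iloc[:, 1 if feats.shape[1] > 1 else 0].astype(str)
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    # optional flag columns appended after the canonical three
    flag_cols = ("mito", "ribo", "sex")
    for k, col in enumerate(flag_cols, start=3):
        if feats.shape[1] > k:
            var[col] = feats.iloc[:, k].astype(str).str.lower().isin(["true", "1"]).to_numpy()

    barcodes = pd.read_csv(src / _BARCODES, header=None).iloc[:, 0].astype(str)
    meta_path = src / _METADATA
    if meta_path.exists():
        obs = pd.read_csv(meta_path, sep="\t", dtype={"barcode": str}).set_index("barcode")
        obs = obs.loc[barcodes]
    else:
        obs = pd.DataFrame(index=pd.Index(barcodes, name="barcode"))
    obs.index.name = "barcode"
    return CountMatrix(X=X, obs=obs, var=var)
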