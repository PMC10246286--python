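"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import striatax as st
from striatax.core import CountMatrix


@pytest.fixture(scope="session")
def small_sim():
    """~800-cell two-region dataset with 4 subclasses in 2 classes."""
    cfg = st.simulate.preset_taxonomy_config(
        n_donors=2, cells_per_sample=200, n_genes=600, n_classes=2,
        baseline_mean=1.0, seed=101,
    )
    matrix, truth = st.simulate.simulate_dataset(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def qc_sim():
    """Six-type dataset carrying the canonical QC marker panels."""
    cfg = st.simulate.preset_qc_config(cells_per_sample=1500, doublet_rate=0.06, seed=2)
    matrix, truth = st.simulate.simulate_dataset(cfg)
    return cfg, matrix, truth


def make_matrix(counts, samples=None, regions=None, gene_names=None, mito=None):
    """Build a CountMatrix from a dense array with minimal metadata."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    obs = pd.DataFrame(index=pd.Index([f"c{i}" for i in range(n_cells)], name="barcode"))
    obs["sample"] = samples if samples is not None else "s1"
    obs["region"] = regions if regions is not None else "CN"
    genes = gene_names if gene_names is not None else [f"g{j}" for j in range(n_genes)]
    var = pd.DataFrame(index=pd.Index(genes, name="gene"))
    if mito is not None:
        var["mito"] = mito
    return CountMatrix(X=sp.csr_matrix(counts), obs=obs, var=var)


@pytest.fixture
def tiny_matrix():
    return make_matrix(np.array([[1, 1, 2], [2, 2, 4]]))
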