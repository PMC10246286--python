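"""Single-latent-factor model of continuous within-subclass variation.

Fits ``x = w z + eps`` with ``z ~ N(0, 1)`` and ``eps ~ N(0, diag(psi))`` by
EM on centered log-normalized expression of the most variable genes within
one (subclass, region) stratum.  Cells are scored by the posterior mean of
``z`` and genes ranked by their signed weight ``w``.

Identifiability: the model is invariant under ``(w, z) -> (-w, -z)`` and a
scale swap between ``w`` and ``z``; fits are canonicalized to unit-norm
weights with the largest-|w| gene positive and the scale absorbed into the
scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import CountMatrix
from .taxonomy import select_hvg

logger = logging.getLogger(__name__)

__all__ = ["FactorModel", "prepare_gradient_input", "fit_factor_model", "top_weight_genes"]

PSI_FLOOR = 1e-10


@dataclass
class FactorModel:
    genes: list[str]
    mean: np.ndarray  # per-gene mean removed before fitting
    weights: np.ndarray  # unit-norm, canonical sign
    psi: np.ndarray  # per-gene noise variances (> 0)
    scores: np.ndarray  # per-cell posterior mean factor values
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True


def prepare_gradient_input(norm: CountMatrix, subclass: str, region: str,
                           labels: pd.Series | np.ndarray | None = None,
                           n_hvg: int = 1200, min_cells: int = 50,
                           ) -> tuple[np.ndarray, list[str], pd.Index]:
    """Center the HVG submatrix of one (subclass, region) stratum.

    ``labels`` gives per-cell subclass assignments (defaults to an
    ``obs['subclass']`` column).  Sex-linked, mitochondrial and riboprotein
    genes are removed before HVG selection.  Returns
    ``(centered cells x genes array, gene names, cell barcodes)``.
    """
    lab = np.asarray(labels) if labels is not None else norm.obs["subclass"].to_numpy()
    mask = (lab == subclass) & (norm.obs["region"].to_numpy() == region)
    n = int(mask.sum())
    if n < min_cells:
        raise ValueError(
            f"stratum ({subclass!r}, {region!r}) has {n} cells; need >= {min_cells}"
        )
    sub = norm.subset_cells(mask)
    eligible = ~sub.flagged_genes()
    expressed = np.asarray((sub.X > 0).sum(axis=0)).ravel() > 0
    n_eligible = int((eligible & expressed).sum())
    k = n_hvg
    if n_hvg > n_eligible:
        logger.warning("requested %d HVGs but only %d eligible genes; keeping all",
                       n_hvg, n_eligible)
        k = n_eligible
    genes = select_hvg(sub, k, exclude_flagged=True)
    idx = [sub.var.index.get_loc(g) for g in genes]
    X = np.asarray(sub.X[:, idx].todense())
    X = X - X.mean(axis=0, keepdims=True)
    return X, genes, sub.obs.index


def _loglik(Xc: np.ndarray, w: np.ndarray, psi: np.ndarray) -> float:
    """Gaussian log-likelihood under C = w w' + diag(psi), via Woodbury."""
    n, p = Xc.shape
    inv_psi = 1.0 / psi
    q = float((w**2 * inv_psi).sum())
    logdet = float(np.log(psi).sum() + np.log1p(q))
    # tr(C^-1 S) with S = X'X / n, using C^-1 = Psi^-1 - Psi^-1 w w' Psi^-1/(1+q)
    t1 = float((Xc**2 * inv_psi).sum() / n)
    proj = Xc @ (w * inv_psi)
    t2 = float((proj**2).sum() / n) / (1.0 + q)
    trace = t1 - t2
    return -0.5 * n * (p * np.log(2 * np.pi) + logdet + trace)


def fit_factor_model(Xc: np.ndarray, tol: float = 1e-6, max_iter: int = 1000,
                     seed: int = 0) -> FactorModel:
    """Maximum-likelihood single-factor fit by EM with spectral initialization.

    ``Xc`` is a centered cells x genes array.  The weight vector is
    initialised from the leading right singular vector of ``Xc`` plus
    seed-controlled jitter; convergence is declared when the log-likelihood
    gain drops below ``tol``.  The log-likelihood trace is recorded every
    iteration and is non-decreasing up to floating-point error.
    """
    Xc = np.asarray(Xc, dtype=float)
    n, p = Xc.shape
    if p < 2 or n < 3:
        raise ValueError("need at least 2 genes and 3 cells")
    rng = np.random.default_rng(seed)

    # spectral start: leading singular direction scaled to its share of variance
    try:
        from scipy.sparse.linalg import svds
        u, s, vt = svds(Xc, k=1, random_state=rng) if min(n, p) > 2 else (None, None, None)
    except Exception:  # pragma: no cover - tiny inputs
        u = None
    if u is None:
        _, s_full, vt_full = np.linalg.svd(Xc, full_matrices=False)
        s, vt = s_full[:1], vt_full[:1]
    w = vt[0] * (s[0] / np.sqrt(n))
    w = w + rng.normal(0.0, 1e-6 * (np.abs(w).max() + 1e-12), size=p)
    var = Xc.var(axis=0)
    psi = np.maximum(var - w**2, 1e-3 * np.maximum(var, 1e-6))
    psi = np.maximum(psi, PSI_FLOOR)

    trace: list[float] = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        inv_psi = 1.0 / psi
        q = float((w**2 * inv_psi).sum())
        v_post = 1.0 / (1.0 + q)  # posterior variance of z
        m = (Xc @ (w * inv_psi)) * v_post  # posterior means, length n

        ll = _loglik(Xc, w, psi)
        trace.append(ll)
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll

        ez2 = float((m**2).sum()) + n * v_post
        xw = Xc.T @ m  # per-gene sum of x * E[z]
        w = xw / ez2
        psi = (Xc**2).sum(axis=0) / n - (w * xw) / n
        psi = np.maximum(psi, PSI_FLOOR)
    if not converged:
        logger.warning("factor EM hit max_iter=%d without converging", max_iter)

    # final posterior scores, then canonicalize sign and scale
    inv_psi = 1.0 / psi
    q = float((w**2 * inv_psi).sum())
    m = (Xc @ (w * inv_psi)) / (1.0 + q)
    norm_w = float(np.linalg.norm(w))
    if norm_w == 0:
        norm_w = 1.0
    w_unit = w / norm_w
    scores = m * norm_w
    top = int(np.argmax(np.abs(w_unit)))
    if w_unit[top] < 0:
        w_unit = -w_unit
        scores = -scores
    return FactorModel(genes=[], mean=np.zeros(p), weights=w_unit, psi=psi,
                       scores=scores, loglik_trace=trace, converged=converged)


def top_weight_genes(model: FactorModel, genes: list[str] | None, k: int
                     ) -> tuple[list[tuple[str, float]], list[tuple[str, float]]]:
    """Top-k and bottom-k genes by signed factor weight (ties by gene name)."""
    names = genes if genes is not None else model.genes
    if k > len(model.weights):
        raise ValueError(f"k={k} exceeds gene count {len(model.weights)}")
    order = sorted(range(len(names)), key=lambda j: (-model.weights[j], names[j]))
    top = [(names[j], float(model.weights[j])) for j in order[:k]]
    bottom = [(names[j], float(model.weights[j])) for j in order[-k:]][::-1]
    return top, bottom
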