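"""Pseudobulk regional differential expression and over-representation.

Counts are aggregated per (sample, region) for a chosen class, then tested
gene-by-gene with a negative-binomial GLM likelihood-ratio test:

    log mu = offset(log library size) + b0 + b1 * region,  Var = mu + phi mu^2

The per-gene dispersion ``phi`` maximizes the Cox-Reid adjusted profile
likelihood under the full model (optionally shrunk toward a mean-dispersion
trend), the LRT compares full vs. intercept-only fits against chi-square(1),
and p-values are BH-adjusted.  DEG selection and hypergeometric
over-representation against user-supplied gene sets follow.

All gene-wise fits are vectorized: IRLS solves the shared 2-column design in
closed form across genes simultaneously, so thousands of genes fit in
seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .core import CountMatrix
from .stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "PseudobulkMatrix",
    "pseudobulk",
    "nb_glm_lrt",
    "select_degs",
    "ora_hypergeom",
]

MIN_DISPERSION = 1e-8


@dataclass
class PseudobulkMatrix:
    """Gene x (sample, region) aggregated counts with column metadata."""

    counts: pd.DataFrame  # genes x columns
    meta: pd.DataFrame  # per column: sample, region, n_cells, lib_size

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.meta.index):
            raise ValueError("counts columns and meta index must align")


def pseudobulk(matrix: CountMatrix, labels: pd.Series | np.ndarray, cls: str,
               min_cells: int = 10) -> PseudobulkMatrix:
    """Sum raw counts of class ``cls`` cells per (sample, region) column.

    Columns with fewer than ``min_cells`` contributing cells are dropped with
    a warning; fewer than two remaining columns per region is an error.
    """
    lab = np.asarray(labels)
    mask = lab == cls
    if not mask.any():
        raise ValueError(f"no cells labeled {cls!r}")
    obs = matrix.obs.loc[mask, ["sample", "region"]]
    sub = matrix.subset_cells(mask)

    cols, col_meta = [], []
    groups = obs.reset_index(drop=True).groupby(["sample", "region"], sort=True).indices
    for (sample, region), idx in groups.items():
        if len(idx) < min_cells:
            logger.warning("pseudobulk column %s/%s dropped: only %d cells",
                           sample, region, len(idx))
            continue
        col = np.asarray(sub.X[idx].sum(axis=0)).ravel().astype(np.int64)
        cols.append(col)
        col_meta.append((str(sample), str(region), len(idx), int(col.sum())))
    if not col_meta:
        raise ValueError(f"no pseudobulk column retained for class {cls!r}")
    meta = pd.DataFrame(col_meta, columns=["sample", "region", "n_cells", "lib_size"])
    meta.index = pd.Index(
        [f"{s}|{r}" for s, r in zip(meta["sample"], meta["region"])], name="column"
    )
    counts = pd.DataFrame(np.column_stack(cols), index=matrix.var.index, columns=meta.index)
    per_region = meta["region"].value_counts()
    if (per_region < 2).any() or len(per_region) < 2:
        raise ValueError(
            f"need >=2 pseudobulk columns in each of two regions, got {per_region.to_dict()}"
        )
    return PseudobulkMatrix(counts=counts, meta=meta)


# ----------------------------------------------------------------------
# vectorized NB GLM machinery
# ----------------------------------------------------------------------
def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row-wise NB2 log-likelihood; alpha -> 0 handled as Poisson."""
    alpha = np.maximum(alpha, MIN_DISPERSION)[:, None]
    r = 1.0 / alpha
    return (
        gammaln(y + r) - gammaln(r) - gammaln(y + 1)
        + r * np.log(r / (r + mu))
        + y * np.log(mu / (r + mu) + 1e-300)
    ).sum(axis=1)


def _irls(y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: np.ndarray,
          with_slope: bool, max_iter: int = 60, tol: float = 1e-10):
    """Vectorized IRLS across genes for the shared two-column design.

    Returns ``(b0, b1, mu, cr_logdet, converged)`` where ``cr_logdet`` is
    log det(X' W X) of the full design (used by the Cox-Reid adjustment).
    """
    G, n = y.shape
    alpha_col = np.maximum(alpha, MIN_DISPERSION)[:, None]
    base = np.log(np.maximum(y.sum(axis=1), 0.5) / np.exp(offset).sum())
    b0 = base.copy()
    b1 = np.zeros(G)
    converged = np.zeros(G, dtype=bool)
    for _ in range(max_iter):
        eta = offset[None, :] + b0[:, None] + (b1[:, None] * x[None, :] if with_slope else 0.0)
        eta = np.clip(eta, -50, 50)
        mu = np.exp(eta)
        W = mu / (1.0 + alpha_col * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        if with_slope:
            S00 = W.sum(axis=1)
            S01 = (W * x).sum(axis=1)
            S11 = S01  # x is 0/1 so x*x == x
            t0 = (W * z).sum(axis=1)
            t1 = (W * x * z).sum(axis=1)
            det = S00 * S11 - S01**2
            bad = det <= 1e-12
            det_safe = np.where(bad, 1.0, det)
            nb0 = (S11 * t0 - S01 * t1) / det_safe
            nb1 = (S00 * t1 - S01 * t0) / det_safe
            nb0 = np.where(bad, b0, nb0)
            nb1 = np.where(bad, b1, nb1)
        else:
            S00 = W.sum(axis=1)
            nb0 = (W * z).sum(axis=1) / np.maximum(S00, 1e-300)
            nb1 = b1
        delta = np.maximum(np.abs(nb0 - b0), np.abs(nb1 - b1) if with_slope else 0.0)
        b0, b1 = nb0, nb1
        converged = delta < tol
        if converged.all():
            break
    eta = offset[None, :] + b0[:, None] + (b1[:, None] * x[None, :] if with_slope else 0.0)
    eta = np.clip(eta, -50, 50)
    mu = np.exp(eta)
    W = mu / (1.0 + alpha_col * mu)
    S00 = W.sum(axis=1)
    S01 = (W * x).sum(axis=1)
    with np.errstate(invalid="ignore"):
        cr_logdet = np.log(np.maximum(S00 * S01 - S01**2, 1e-300))
    return b0, b1, mu, cr_logdet, converged


def _estimate_dispersion(y: np.ndarray, x: np.ndarray, offset: np.ndarray,
                         grid: np.ndarray, prior_df: float = 10.0,
                         window: int = 101) -> np.ndarray:
    """Per-gene dispersion by moderated Cox-Reid adjusted profile likelihood.

    Each gene maximizes its own CR-APL plus ``prior_df / residual_df`` times
    the mean CR-APL of genes with similar mean abundance (a rolling window
    over abundance-sorted genes).  The moderation pools information across
    genes exactly where the per-gene profile is flat, stabilizing small-
    sample estimates; ``prior_df = 0`` recovers the raw per-gene maximum.
    """
    G, n = y.shape
    apl = np.full((len(grid), G), -np.inf)
    for i, a in enumerate(grid):
        alpha = np.full(G, a)
        _, _, mu, cr_logdet, _ = _irls(y, x, offset, alpha, with_slope=True)
        apl[i] = _nb_loglik(y, mu, alpha) - 0.5 * cr_logdet

    residual_df = max(n - 2, 1)
    if prior_df > 0 and G > 1:
        from scipy.ndimage import uniform_filter1d

        order = np.argsort(y.mean(axis=1), kind="mergesort")
        win = int(min(window, G))
        prior = np.empty_like(apl)
        prior[:, order] = uniform_filter1d(apl[:, order], size=win, axis=1, mode="nearest")
        score = apl + (prior_df / residual_df) * prior
    else:
        score = apl

    best = score.argmax(axis=0)
    log_grid = np.log(grid)
    alpha_hat = grid[best].copy()
    # quadratic refinement in log-dispersion where an interior maximum exists
    interior = (best > 0) & (best < len(grid) - 1)
    idx = np.flatnonzero(interior)
    if idx.size:
        b = best[idx]
        y0, y1, y2 = score[b - 1, idx], score[b, idx], score[b + 1, idx]
        x1 = log_grid[b]
        step = log_grid[b] - log_grid[b - 1]
        denom = (y0 - 2 * y1 + y2)
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        alpha_hat[idx] = np.exp(x1 + shift * step)
    return np.maximum(alpha_hat, MIN_DISPERSION)


def nb_glm_lrt(pb: PseudobulkMatrix, region_order: tuple[str, str] = ("CN", "Pu"),
               prior_df: float = 10.0) -> pd.DataFrame:
    """Per-gene NB-GLM likelihood-ratio test of the region effect.

    The region covariate is coded 0 for ``region_order[0]`` and 1 for
    ``region_order[1]``, so a positive log fold change means higher
    expression in the second region.  All-zero genes are excluded (and
    reported via the ``tested`` column being absent).  Returns a frame
    indexed by gene with columns beta, log2_fc, dispersion, lrt, p, p_adj,
    converged.
    """
    meta = pb.meta
    regions = set(meta["region"])
    if len(regions) < 2:
        raise ValueError("design not estimable: only one region present")
    unknown = regions - set(region_order)
    if unknown:
        raise ValueError(f"unexpected region labels {sorted(unknown)}")
    x = (meta["region"] == region_order[1]).to_numpy(dtype=float)
    offset = np.log(meta["lib_size"].to_numpy(dtype=float))

    Y = pb.counts.to_numpy(dtype=float)
    nonzero = Y.sum(axis=1) > 0
    n_dropped = int((~nonzero).sum())
    if n_dropped:
        logger.info("excluding %d all-zero genes from testing", n_dropped)
    y = Y[nonzero]

    grid = np.geomspace(1e-6, 30.0, 49)
    alpha_used = _estimate_dispersion(y, x, offset, grid, prior_df=prior_df)

    b0f, b1f, muf, _, conv_f = _irls(y, x, offset, alpha_used, with_slope=True)
    b0n, _, mun, _, conv_n = _irls(y, x, offset, alpha_used, with_slope=False)
    ll_full = _nb_loglik(y, muf, alpha_used)
    ll_null = _nb_loglik(y, mun, alpha_used)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    converged = conv_f & conv_n
    p = np.where(converged, sps.chi2.sf(lrt, df=1), np.nan)

    padj = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    padj[ok] = bh_adjust(p[ok])

    res = pd.DataFrame(
        {
            "beta": b1f,
            "log2_fc": b1f / np.log(2.0),
            "dispersion": alpha_used,
            "lrt": lrt,
            "p": p,
            "p_adj": padj,
            "converged": converged,
        },
        index=pb.counts.index[nonzero],
    )
    res.index.name = "gene"
    return res


def select_degs(res: pd.DataFrame, lfc: float = 0.5, alpha: float = 0.05
                ) -> tuple[list[str], list[str]]:
    """Strict DEG selection: |log2 FC| > ``lfc`` and adjusted p < ``alpha``."""
    sig = res["p_adj"] < alpha
    up = res.index[sig & (res["log2_fc"] > lfc)].tolist()
    down = res.index[sig & (res["log2_fc"] < -lfc)].tolist()
    return up, down


def ora_hypergeom(selected: list[str], sets: dict[str, list[str]],
                  universe: list[str], p_cut: float = 0.1) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per gene set.

    ``p = P(X >= k)`` for overlap ``k`` between the selected genes and the
    set (both intersected with the universe).  Terms with raw ``p < p_cut``
    are flagged; results are sorted by p then term name.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected) & uni
    stray = set(selected) - uni
    if stray:
        logger.warning("%d selected genes outside the universe were ignored", len(stray))
    N, n = len(uni), len(sel)
    rows = []
    for term in sorted(sets):
        members = set(sets[term]) & uni
        K = len(members)
        k = len(members & sel)
        p = float(sps.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, k, K, n, N, p, p < p_cut))
    out = pd.DataFrame(rows, columns=["term", "overlap", "set_size",
                                      "selection_size", "universe_size", "p", "selected"])
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
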