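"""Five-part nucleus quality control with an auditable per-stage report.

Stages, applied in this fixed order:

1. multi-run consensus doublet calling (a simulated-doublet kNN scorer run
   repeatedly; cells called in more than a configured fraction of the runs
   are flagged),
2. hard depth/complexity/mitochondrial filters,
3. an outlier rule on the quadratic fit of log gene count vs. log UMI count,
4. multi-type marker-score doublet flags via two-Gaussian mixture thresholds,
5. removal of cells expressing regional contamination markers.

A cell failing several rules is attributed to the first failing stage so the
report reads as a waterfall; the filtered matrix excludes any flagged cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix
from .preprocess import normalize_log

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "QCReport",
    "QCError",
    "MixtureFit",
    "mixture_threshold",
    "mixture_boundary",
    "marker_score",
    "score_doublets_once",
    "consensus_doublets",
    "hard_filters",
    "fit_gene_umi_polynomial",
    "multitype_doublet_flags",
    "contamination_filter",
    "run_qc",
    "DEFAULT_TYPE_PANELS",
]

#: canonical marker panels for the six broad cell types scored during QC
DEFAULT_TYPE_PANELS: dict[str, list[str]] = {
    "Astrocytes": ["AQP4", "ADGRV1"],
    "Microglia": ["CSF1R", "FYB1"],
    "Oligodendrocytes": ["MBP", "MOG", "MAG"],
    "OPC": ["PTPRZ1", "PDGFRA", "VCAN"],
    "Vascular": ["EBF1", "ABCB1", "ABCA9"],
    "Neurons": ["MEG3"],
}

STAGE_ORDER = ("doublet_consensus", "depth_low", "depth_high", "mito",
               "poly_outlier", "multitype", "contamination")


class QCError(RuntimeError):
    """QC could not proceed; carries the partial report when available."""

    def __init__(self, message: str, report: "QCReport | None" = None):
        super().__init__(message)
        self.report = report


@dataclass
class QCThresholds:
    min_umi: int = 500
    min_genes: int = 1200
    max_umi: int = 250_000
    max_genes: int = 15_000
    max_mito_fraction: float = 0.10
    doublet_runs: int = 100
    doublet_consensus_fraction: float = 0.10
    doublet_k: int = 10
    poly_degree: int = 2
    poly_residual_limit: float = 2000.0  # gene-count units after back-transform
    mixture_sd_multiplier: float = 4.0
    contamination_markers: tuple[str, ...] = ("NEUROD2", "TMEM155", "CARTPT", "SLC17A7")
    contamination_cutoff: float = 1.0  # log-normalized expression
    min_mixture_scores: int = 50

    def __post_init__(self) -> None:
        if not self.min_umi < self.max_umi:
            raise ValueError("min_umi must be < max_umi")
        if not self.min_genes < self.max_genes:
            raise ValueError("min_genes must be < max_genes")
        if not 0 < self.doublet_consensus_fraction < 1:
            raise ValueError("doublet_consensus_fraction must lie in (0, 1)")
        if self.mixture_sd_multiplier <= 0:
            raise ValueError("mixture_sd_multiplier must be positive")


@dataclass
class QCReport:
    """Per-cell flags, per-stage exclusion counts and fitted parameters."""

    flags: pd.DataFrame
    stage_counts: dict[str, int]
    poly_coefficients: np.ndarray | None = None
    mixture_fits: dict[str, "MixtureFit"] = field(default_factory=dict)
    type_calls: pd.Series | None = None

    @property
    def passed(self) -> pd.Series:
        return ~self.flags.any(axis=1)


# ----------------------------------------------------------------------
# two-component Gaussian mixture thresholding
# ----------------------------------------------------------------------
@dataclass
class MixtureFit:
    """Two-Gaussian EM fit with the derived low-mean + k*SD threshold."""

    means: tuple[float, float]  # (low, high)
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    unimodal: bool = False
    n_iter: int = 0


def _fit_two_gaussians(x: np.ndarray, tol: float = 1e-6, max_iter: int = 500):
    """Deterministic EM for a two-component univariate Gaussian mixture.

    Initialised from the 25th/75th percentiles (a quantile k-means seed).
    Returns ``None`` when the fit degenerates (component weight < 1e-3 or
    SD < 1e-6), which callers interpret as a unimodal distribution.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) < 1e-12:
        return None
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    sd = np.full(2, max(np.std(x), 1e-6))
    w = np.array([0.5, 0.5])
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_pdf = sps.norm.logpdf(x[:, None], mu[None, :], sd[None, :]) + np.log(w)[None, :]
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = float(lse.sum())
        resp = np.exp(log_pdf - lse[:, None])
        nk = resp.sum(axis=0)
        if nk.min() < 1e-3 * len(x):
            return None
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, 0.0))
        if sd.min() < 1e-6 or w.min() < 1e-3:
            return None
        if abs(ll - prev_ll) < tol:
            break
        prev_ll = ll
    return mu, sd, w, n_iter


def mixture_threshold(scores: np.ndarray, thresholds: QCThresholds | None = None) -> MixtureFit:
    """Threshold = mean of the low-mean component + k times its SD.

    Ties in component means are broken by the smaller variance being "low".
    A degenerate EM fit is reported as ``unimodal=True`` with a +inf
    threshold so that no cell is called positive.
    """
    thresholds = thresholds or QCThresholds()
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    if finite.size < thresholds.min_mixture_scores:
        raise ValueError(
            f"need at least {thresholds.min_mixture_scores} finite scores, got {finite.size}"
        )
    fit = _fit_two_gaussians(finite)
    if fit is None:
        return MixtureFit((np.nan, np.nan), (np.nan, np.nan), (np.nan, np.nan),
                          np.inf, unimodal=True)
    mu, sd, w, n_iter = fit
    order = np.lexsort((sd, mu))  # smaller mean first; ties by smaller SD
    lo, hi = order[0], order[1]
    thr = float(mu[lo] + thresholds.mixture_sd_multiplier * sd[lo])
    return MixtureFit(
        means=(float(mu[lo]), float(mu[hi])),
        sds=(float(sd[lo]), float(sd[hi])),
        weights=(float(w[lo]), float(w[hi])),
        threshold=thr,
        n_iter=n_iter,
    )


def mixture_boundary(scores: np.ndarray, thresholds: QCThresholds | None = None) -> float:
    """Equal-posterior decision boundary between the two mixture components.

    Used by the doublet scorer, whose synthetic-score distribution has a
    homotypic (low) and a heterotypic (high) mode; the boundary classifies a
    score as belonging to the high component.  Returns +inf for a unimodal
    fit (no call).
    """
    thresholds = thresholds or QCThresholds()
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    if finite.size < thresholds.min_mixture_scores:
        raise ValueError(
            f"need at least {thresholds.min_mixture_scores} finite scores, got {finite.size}"
        )
    fit = _fit_two_gaussians(finite)
    if fit is None:
        return np.inf
    mu, sd, w, _ = fit
    order = np.lexsort((sd, mu))
    lo, hi = order[0], order[1]
    xs = np.linspace(mu[lo], mu[hi], 1001)
    log_lo = np.log(w[lo]) + sps.norm.logpdf(xs, mu[lo], sd[lo])
    log_hi = np.log(w[hi]) + sps.norm.logpdf(xs, mu[hi], sd[hi])
    above = np.flatnonzero(log_hi >= log_lo)
    if above.size == 0:
        return float(0.5 * (mu[lo] + mu[hi]))
    return float(xs[above[0]])


# ----------------------------------------------------------------------
# marker scores
# ----------------------------------------------------------------------
def marker_score(matrix: CountMatrix, panel: list[str],
                 normalized: CountMatrix | None = None) -> np.ndarray:
    """Per-cell mean log-normalized expression over a marker panel.

    Panel genes absent from the matrix are dropped with a warning; an empty
    effective panel is an error.  Pass a pre-normalized matrix to avoid
    recomputing the normalization for every panel.
    """
    present = [g for g in panel if g in matrix.var.index]
    missing = sorted(set(panel) - set(present))
    if missing:
        logger.warning("panel genes missing from matrix, dropped: %s", missing)
    if not present:
        raise ValueError(f"no panel gene present in matrix: {panel}")
    norm = normalized if normalized is not None else normalize_log(matrix)
    idx = [norm.var.index.get_loc(g) for g in present]
    block = norm.X[:, idx].toarray()
    return block.mean(axis=1)


# ----------------------------------------------------------------------
# doublets
# ----------------------------------------------------------------------
def score_doublets_once(matrix: CountMatrix, seed: int, k: int = 10,
                        n_pcs: int = 30, return_synthetic: bool = False):
    """Simulated-doublet kNN score in [0, 1] for every cell.

    Simulates as many synthetic doublets as there are cells by summing
    random cell pairs, embeds originals + synthetics with PCA on
    log-normalized counts, and scores each original cell by the fraction of
    synthetic doublets among its k nearest neighbors.  With
    ``return_synthetic`` the synthetic doublets' own scores are returned as
    well; their distribution (homotypic vs heterotypic pairs) is what the
    per-run calling threshold is derived from.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    n = matrix.n_cells
    if n < 2 * k:
        raise ValueError(f"need at least {2 * k} cells for k={k}")
    rng = np.random.default_rng(seed)
    left = rng.integers(0, n, size=n)
    right = rng.integers(0, n, size=n)
    clash = left == right
    right[clash] = (right[clash] + 1) % n
    synth = matrix.X[left] + matrix.X[right]

    import scipy.sparse as sp

    combined = sp.vstack([matrix.X, synth]).tocsr()
    totals = np.asarray(combined.sum(axis=1)).ravel()
    scale = np.where(totals > 0, 1e4 / np.maximum(totals, 1), 1.0)
    combined = sp.diags(scale) @ combined
    combined.data = np.log1p(combined.data)
    dense = np.asarray(combined.todense())

    n_comp = min(n_pcs, dense.shape[1] - 1, dense.shape[0] - 1)
    emb = PCA(n_components=n_comp, svd_solver="randomized",
              random_state=seed).fit_transform(dense)

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neighbor = idx[:, 1:]  # drop self (distance 0, always first)
    scores = (neighbor >= n).mean(axis=1)
    if return_synthetic:
        return scores[:n], scores[n:]
    return scores[:n]


def consensus_doublets(matrix: CountMatrix, thresholds: QCThresholds,
                       base_seed: int = 0) -> np.ndarray:
    """Flag cells called as doublets in more than the consensus fraction of runs.

    Runs the scorer ``doublet_runs`` times per sample with seeds
    ``base_seed .. base_seed + runs - 1``; each run derives a binary call by
    fitting a two-Gaussian mixture to that run's synthetic doublet scores,
    whose homotypic/heterotypic components make the distribution bimodal,
    and calling cells above the components' equal-posterior boundary (a
    unimodal fit calls no cell).  The flag uses a strict inequality,
    matching "more than".
    """
    if thresholds.doublet_runs < 1:
        raise ValueError("doublet_runs must be >= 1")
    flags = np.zeros(matrix.n_cells, dtype=bool)
    samples = matrix.obs["sample"] if "sample" in matrix.obs.columns else pd.Series(
        "all", index=matrix.obs.index)
    for sample in samples.unique():
        cell_idx = np.flatnonzero((samples == sample).to_numpy())
        sub = matrix.subset_cells(cell_idx)
        calls = np.zeros(len(cell_idx), dtype=np.int64)
        for run in range(thresholds.doublet_runs):
            scores, synth_scores = score_doublets_once(
                sub, seed=base_seed + run, k=thresholds.doublet_k, return_synthetic=True)
            boundary = mixture_boundary(synth_scores, thresholds)
            calls += scores > boundary
        frac = calls / thresholds.doublet_runs
        flags[cell_idx] = frac > thresholds.doublet_consensus_fraction
    return flags


# ----------------------------------------------------------------------
# deterministic rules
# ----------------------------------------------------------------------
def hard_filters(matrix: CountMatrix, thresholds: QCThresholds) -> pd.DataFrame:
    """Depth and mitochondrial-content flags (all strict inequalities)."""
    umi = matrix.total_counts()
    genes = matrix.genes_detected()
    mito_mask = matrix.gene_flag("mito")
    mito_counts = np.asarray(matrix.X[:, mito_mask].sum(axis=1)).ravel() if mito_mask.any() \
        else np.zeros(matrix.n_cells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(umi > 0, mito_counts / np.maximum(umi, 1), 0.0)
    return pd.DataFrame(
        {
            "depth_low": (umi < thresholds.min_umi) | (genes < thresholds.min_genes),
            "depth_high": (umi > thresholds.max_umi) | (genes > thresholds.max_genes),
            "mito": mito_frac > thresholds.max_mito_fraction,
        },
        index=matrix.obs.index,
    )


def fit_gene_umi_polynomial(
    matrix: CountMatrix,
    thresholds: QCThresholds,
    eligible: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Quadratic fit of log gene count on log UMI count; flag curve outliers.

    The fit uses only ``eligible`` cells (callers pass the survivors of the
    doublet-consensus and hard filters).  A cell is flagged when its observed
    gene count differs from the back-transformed prediction
    ``exp(fit(log UMI))`` by more than ``poly_residual_limit`` genes.
    Returns ``(coefficients_highest_first, flags)``.
    """
    umi = matrix.total_counts().astype(float)
    genes = matrix.genes_detected().astype(float)
    if eligible is None:
        eligible = np.ones(matrix.n_cells, dtype=bool)
    usable = eligible & (umi > 0) & (genes > 0)
    if usable.sum() < 10:
        raise QCError("fewer than 10 eligible cells for the gene~UMI polynomial; "
                      "skip this rule or loosen upstream filters")
    coeffs = np.polyfit(np.log(umi[usable]), np.log(genes[usable]), thresholds.poly_degree)
    flags = np.zeros(matrix.n_cells, dtype=bool)
    ok = (umi > 0) & (genes > 0)
    pred = np.exp(np.polyval(coeffs, np.log(umi[ok])))
    flags[ok] = np.abs(genes[ok] - pred) > thresholds.poly_residual_limit
    return coeffs, flags


def multitype_doublet_flags(
    matrix: CountMatrix,
    type_panels: dict[str, list[str]] | None = None,
    thresholds: QCThresholds | None = None,
) -> tuple[np.ndarray, pd.Series, dict[str, MixtureFit]]:
    """Flag cells scoring above the mixture threshold for two or more types.

    Returns ``(flags, per-cell type call, per-type mixture fits)``.  The type
    call is the type name for cells positive for exactly one type, "doublet"
    for multi-positive cells and "" otherwise.
    """
    type_panels = type_panels or DEFAULT_TYPE_PANELS
    thresholds = thresholds or QCThresholds()
    if len(type_panels) < 2:
        raise ValueError("need at least two type panels")
    norm = normalize_log(matrix)
    positives = {}
    fits: dict[str, MixtureFit] = {}
    for type_name in sorted(type_panels):
        try:
            scores = marker_score(matrix, type_panels[type_name], normalized=norm)
        except ValueError:
            logger.warning("no panel gene for type %s present; treating as all-negative",
                           type_name)
            positives[type_name] = np.zeros(matrix.n_cells, dtype=bool)
            continue
        fit = mixture_threshold(scores, thresholds)
        fits[type_name] = fit
        positives[type_name] = np.zeros(matrix.n_cells, dtype=bool) if fit.unimodal \
            else scores > fit.threshold
    pos = pd.DataFrame(positives, index=matrix.obs.index)
    n_pos = pos.sum(axis=1)
    flags = (n_pos >= 2).to_numpy()
    calls = pd.Series("", index=matrix.obs.index, dtype=object)
    single = n_pos == 1
    if single.any():
        calls[single] = pos.loc[single].idxmax(axis=1)
    calls[n_pos >= 2] = "doublet"
    return flags, calls, fits


def contamination_filter(matrix: CountMatrix, thresholds: QCThresholds,
                         normalized: CountMatrix | None = None) -> np.ndarray:
    """Flag cells expressing any regional contamination marker above cutoff."""
    norm = normalized if normalized is not None else normalize_log(matrix)
    flags = np.zeros(matrix.n_cells, dtype=bool)
    for gene in thresholds.contamination_markers:
        if gene not in norm.var.index:
            logger.warning("contamination marker %s absent from matrix", gene)
            continue
        flags |= norm.gene_vector(gene) > thresholds.contamination_cutoff
    return flags


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------
def run_qc(
    matrix: CountMatrix,
    thresholds: QCThresholds | None = None,
    seed: int = 0,
    type_panels: dict[str, list[str]] | None = None,
    skip_doublets: bool = False,
) -> tuple[CountMatrix, QCReport]:
    """Apply all QC stages in order and return the filtered matrix + report.

    Stage order: doublet consensus, hard filters, gene~UMI polynomial,
    multi-type doublets, contamination.  Exclusion counts attribute each
    failing cell to its first failing stage.
    """
    if matrix.n_cells == 0:
        raise QCError("empty matrix")
    thresholds = thresholds or QCThresholds()

    if skip_doublets:
        doublet_flags = np.zeros(matrix.n_cells, dtype=bool)
    else:
        doublet_flags = consensus_doublets(matrix, thresholds, base_seed=seed)
    hard = hard_filters(matrix, thresholds)
    eligible = ~doublet_flags & ~hard.any(axis=1).to_numpy()
    coeffs, poly_flags = fit_gene_umi_polynomial(matrix, thresholds, eligible=eligible)
    multi_flags, type_calls, fits = multitype_doublet_flags(matrix, type_panels, thresholds)
    contam_flags = contamination_filter(matrix, thresholds)

    flags = pd.DataFrame(
        {
            "doublet_consensus": doublet_flags,
            "depth_low": hard["depth_low"].to_numpy(),
            "depth_high": hard["depth_high"].to_numpy(),
            "mito": hard["mito"].to_numpy(),
            "poly_outlier": poly_flags,
            "multitype": multi_flags,
            "contamination": contam_flags,
        },
        index=matrix.obs.index,
    )

    # waterfall: attribute each excluded cell to its first failing stage
    stage_counts: dict[str, int] = {}
    already = np.zeros(matrix.n_cells, dtype=bool)
    for stage in STAGE_ORDER:
        hit = flags[stage].to_numpy() & ~already
        stage_counts[stage] = int(hit.sum())
        already |= hit

    report = QCReport(flags=flags, stage_counts=stage_counts,
                      poly_coefficients=coeffs, mixture_fits=fits, type_calls=type_calls)
    keep = report.passed.to_numpy()
    if not keep.any():
        raise QCError("all cells removed by QC", report=report)
    return matrix.subset_cells(keep), report
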