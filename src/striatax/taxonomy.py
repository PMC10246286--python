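"""Iterative marker-based cell taxonomy.

Covers the classification ladder: log-normalization, dispersion-based
highly-variable-gene selection, PCA/kNN/Louvain clustering, marker-panel
cluster annotation, neuron depth refinement, inhibitory-cluster selection,
one-vs-rest Wilcoxon marker ranking, correlation-threshold merging of
subtypes into classes, the class dendrogram, and functional gene-panel
subsetting.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass, field

import igraph
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .core import CountMatrix
from .preprocess import normalize_log  # noqa: F401  (public re-export)
from .qc import QCThresholds, marker_score, mixture_threshold
from .stats import bh_adjust, rank_sum_test

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanels",
    "normalize_log",
    "select_hvg",
    "embed_and_cluster",
    "annotate_clusters",
    "refine_neurons",
    "select_interneurons",
    "rank_markers_wilcoxon",
    "merge_by_correlation",
    "correlation_dendrogram",
    "subset_gene_panel",
    "dendrogram_to_newick",
    "RECEPTOR_PREFIXES",
]

#: receptor gene-name prefixes for the functional projection panels
RECEPTOR_PREFIXES = ("DRD", "GABR", "CHRN", "CHRM",
                     "GRIA", "GRIN", "GRIK", "GRM", "GRID", "GRIP")


@dataclass
class MarkerPanels:
    """Named marker panels used for cluster annotation and selection."""

    panels: dict[str, list[str]] = field(default_factory=lambda: {
        "Astrocytes": ["AQP4", "ADGRV1"],
        "Microglia": ["CSF1R", "FYB1"],
        "Oligodendrocytes": ["MBP", "MOG", "MAG"],
        "OPC": ["PTPRZ1", "PDGFRA", "VCAN"],
        "Vascular": ["EBF1", "ABCB1", "ABCA9"],
        "Neurons": ["MEG3"],
    })
    inhibitory: list[str] = field(default_factory=lambda: ["GAD1", "GAD2"])
    msn: list[str] = field(default_factory=lambda: ["PPP1R1B", "DRD1", "DRD2", "MEIS2"])
    excitatory: list[str] = field(default_factory=lambda: ["RORB", "SLC17A7"])

    def __post_init__(self) -> None:
        for name, panel in self.panels.items():
            if not panel:
                raise ValueError(f"empty marker panel {name!r}")


# ----------------------------------------------------------------------
# feature selection / embedding
# ----------------------------------------------------------------------
def select_hvg(norm: CountMatrix, n: int, exclude_flagged: bool = True,
               n_bins: int = 20) -> list[str]:
    """Top-n highly variable genes by mean-binned normalized dispersion.

    Dispersion = variance / mean of the normalized expression; genes are
    binned by mean expression (20 bins) and their dispersion z-scored within
    the bin.  Genes carrying the mito/ribo/sex flags are never selected.
    Ties are broken lexicographically by gene name for determinism.
    """
    X = norm.X.tocsc()
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)

    eligible = mean > 0
    if exclude_flagged:
        eligible &= ~norm.flagged_genes()
    if n > eligible.sum():
        raise ValueError(f"requested {n} HVGs but only {int(eligible.sum())} eligible genes")

    # z-score dispersion within mean-expression bins (eligible genes only)
    norm_disp = np.full(norm.n_genes, -np.inf)
    idx = np.flatnonzero(eligible)
    # each bin should hold several genes or the within-bin z-score is vacuous
    q = max(1, min(n_bins, len(idx) // 5))
    bins = pd.qcut(mean[idx], q=q, labels=False, duplicates="drop")
    d = disp[idx]
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = d[sel].mean(), d[sel].std()
        norm_disp[idx[sel]] = (d[sel] - mu) / sd if sd > 0 else 0.0

    order = sorted(idx, key=lambda j: (-norm_disp[j], norm.var.index[j]))
    return [norm.var.index[j] for j in order[:n]]


def _pca_embed(norm: CountMatrix, genes: list[str] | None, n_pcs: int,
               seed: int, standardize: bool = True) -> np.ndarray:
    sub = norm.subset_genes([norm.var.index.get_loc(g) for g in genes]) if genes else norm
    X = np.asarray(sub.X.todense())
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1] - 1)
    return PCA(n_components=n_comp, svd_solver="randomized",
               random_state=seed).fit_transform(X)


def embed_and_cluster(norm: CountMatrix, n_pcs: int = 30, resolution: float = 0.2,
                      seed: int = 0, k: int = 15, genes: list[str] | None = None,
                      ) -> np.ndarray:
    """PCA + kNN graph + Louvain community detection.

    ``norm`` should already be restricted to the genes to embed (or pass
    ``genes``).  Genes are standardized before PCA.  Deterministic for a
    fixed seed.
    """
    if norm.n_cells <= k:
        raise ValueError(f"need more than k={k} cells, got {norm.n_cells}")
    emb = _pca_embed(norm, genes, n_pcs, seed)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = igraph.Graph(n=norm.n_cells, edges=sorted(edges))
    igraph.set_random_number_generator(_random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    igraph.set_random_number_generator(_random)
    return np.asarray(part.membership, dtype=np.int64)


# ----------------------------------------------------------------------
# annotation / selection
# ----------------------------------------------------------------------
def annotate_clusters(matrix: CountMatrix, clusters: np.ndarray,
                      panels: MarkerPanels | dict[str, list[str]] | None = None,
                      normalized: CountMatrix | None = None) -> dict[int, str]:
    """Label each cluster by the marker panel with the highest mean score.

    Ties are broken deterministically by label name (with a warning).
    """
    if panels is None:
        panels = MarkerPanels()
    panel_map = panels.panels if isinstance(panels, MarkerPanels) else panels
    norm = normalized if normalized is not None else normalize_log(matrix)
    scores = {}
    for label in sorted(panel_map):
        try:
            scores[label] = marker_score(matrix, panel_map[label], normalized=norm)
        except ValueError:
            logger.warning("panel %s has no genes in matrix; scored as zero", label)
            scores[label] = np.zeros(matrix.n_cells)
    out: dict[int, str] = {}
    for cl in np.unique(clusters):
        mask = clusters == cl
        means = {label: float(s[mask].mean()) for label, s in scores.items()}
        best = max(means.values())
        winners = sorted(lab for lab, v in means.items() if v == best)
        if len(winners) > 1:
            logger.warning("cluster %s: tied panels %s, using %s", cl, winners, winners[0])
        out[int(cl)] = winners[0]
    return out


def refine_neurons(matrix: CountMatrix, labels: pd.Series | np.ndarray,
                   min_umi: int = 5000, min_genes: int = 3000,
                   max_genes: int = 12000) -> np.ndarray:
    """Keep neuron-labeled cells passing the neuron-specific depth filters.

    Discards neurons with fewer than ``min_umi`` UMIs, fewer than
    ``min_genes`` or more than ``max_genes`` genes (strict inequalities, so
    boundary cells survive).  Returns a boolean mask over cells.
    """
    lab = np.asarray(labels)
    umi = matrix.total_counts()
    genes = matrix.genes_detected()
    return (lab == "Neurons") & (umi >= min_umi) & (genes >= min_genes) & (genes <= max_genes)


def select_interneurons(matrix: CountMatrix, clusters: np.ndarray,
                        panels: MarkerPanels | None = None,
                        thresholds: QCThresholds | None = None,
                        normalized: CountMatrix | None = None) -> np.ndarray:
    """Cells of clusters positive for GAD1/GAD2 and negative for MSN/excitatory.

    Positivity is decided at cluster level: the cluster's mean panel score is
    compared with the two-Gaussian mixture threshold derived from the
    per-cell score distribution.  Returns a boolean cell mask (empty, with a
    warning, when no cluster qualifies).
    """
    panels = panels or MarkerPanels()
    thresholds = thresholds or QCThresholds()
    norm = normalized if normalized is not None else normalize_log(matrix)

    def cluster_positive(panel: list[str]) -> dict[int, bool]:
        try:
            scores = marker_score(matrix, panel, normalized=norm)
        except ValueError:
            return {int(c): False for c in np.unique(clusters)}
        fit = mixture_threshold(scores, thresholds)
        out = {}
        for cl in np.unique(clusters):
            mean_score = float(scores[clusters == cl].mean())
            out[int(cl)] = (not fit.unimodal) and mean_score > fit.threshold
        return out

    inhib = cluster_positive(panels.inhibitory)
    msn = cluster_positive(panels.msn)
    excit = cluster_positive(panels.excitatory)
    good = {cl for cl in inhib if inhib[cl] and not msn[cl] and not excit[cl]}
    if not good:
        logger.warning("no cluster qualifies as interneurons")
    return np.isin(clusters, sorted(good))


# ----------------------------------------------------------------------
# marker ranking
# ----------------------------------------------------------------------
def rank_markers_wilcoxon(norm: CountMatrix, groups: pd.Series | np.ndarray,
                          exact_max: int = 8) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker table per group.

    Returns a tidy frame with columns group, gene, log2_fc, statistic, p,
    p_adj (BH within group).  Log fold changes compare group vs rest means
    of the linear normalized expression with a 1e-9 pseudocount.  Small
    groups (both sides <= ``exact_max``) use the exact permutation null.
    """
    groups = pd.Series(np.asarray(groups), index=norm.obs.index)
    uniq = sorted(groups.unique())
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    sizes = groups.value_counts()
    if (sizes < 2).any():
        raise ValueError("every group needs at least two cells")

    X = np.asarray(norm.X.todense())
    linear = np.expm1(X)
    n, p = X.shape
    results = []
    use_exact = sizes.max() <= exact_max and n - sizes.min() <= exact_max
    if not use_exact:
        ranks = sps.rankdata(X, axis=0)
        tie_terms = np.empty(p)
        for j in range(p):
            _, c = np.unique(X[:, j], return_counts=True)
            tie_terms[j] = (c.astype(float) ** 3 - c).sum()

    for grp in uniq:
        mask = (groups == grp).to_numpy()
        n1 = int(mask.sum())
        n2 = n - n1
        mean_in = linear[mask].mean(axis=0)
        mean_out = linear[~mask].mean(axis=0)
        lfc = np.log2((mean_in + 1e-9) / (mean_out + 1e-9))
        if n1 <= exact_max and n2 <= exact_max:
            stat = np.empty(p)
            pval = np.empty(p)
            for j in range(p):
                stat[j], pval[j] = rank_sum_test(X[mask, j], X[~mask, j], exact_max=exact_max)
        else:
            stat = ranks[mask].sum(axis=0)
            mu = n1 * (n + 1) / 2.0
            var = n1 * n2 / 12.0 * ((n + 1) - tie_terms / (n * (n - 1)))
            with np.errstate(invalid="ignore", divide="ignore"):
                z = np.where(var > 0, (stat - mu) / np.sqrt(np.maximum(var, 1e-300)), 0.0)
            pval = np.minimum(2.0 * sps.norm.sf(np.abs(z)), 1.0)
        padj = bh_adjust(pval)
        results.append(pd.DataFrame({
            "group": grp,
            "gene": norm.var.index,
            "log2_fc": lfc,
            "statistic": stat,
            "p": pval,
            "p_adj": padj,
        }))
    return pd.concat(results, ignore_index=True)


# ----------------------------------------------------------------------
# merging / dendrogram
# ----------------------------------------------------------------------
def _centroids(norm: CountMatrix, groups: np.ndarray) -> pd.DataFrame:
    X = norm.X
    labels = sorted(pd.unique(groups))
    rows = {}
    for g in labels:
        mask = np.asarray(groups) == g
        rows[g] = np.asarray(X[mask].mean(axis=0)).ravel()
    return pd.DataFrame(rows, index=norm.var.index).T  # groups x genes


def merge_by_correlation(norm: CountMatrix, subtypes: pd.Series | np.ndarray,
                         threshold: float = 0.49) -> tuple[dict[str, str], pd.DataFrame]:
    """Join subtypes whose centroid profiles all correlate above threshold.

    Computes mean normalized expression per subtype across all genes and the
    pairwise Pearson correlation matrix; subtypes are grouped greedily (in
    lexicographic order) so that every within-group pair has r strictly
    greater than ``threshold``.  Singletons become their own class.  Returns
    ``(subtype -> class label map, correlation matrix)``; a merged class is
    named by joining its members with "/".
    """
    subtypes = np.asarray(subtypes)
    cent = _centroids(norm, subtypes)
    names = list(cent.index)
    if len(names) == 1:
        return {names[0]: names[0]}, pd.DataFrame([[1.0]], index=names, columns=names)
    corr = pd.DataFrame(np.corrcoef(cent.to_numpy()), index=names, columns=names)

    assigned: dict[str, list[str]] = {}
    taken: set[str] = set()
    for s in sorted(names):
        if s in taken:
            continue
        members = [s]
        for t in sorted(names):
            if t in taken or t == s:
                continue
            if all(corr.loc[t, u] > threshold for u in members):
                members.append(t)
        for m in members:
            taken.add(m)
        cls = "/".join(sorted(members))
        assigned[cls] = members
    merge_map = {m: cls for cls, mem in assigned.items() for m in mem}
    return merge_map, corr


def correlation_dendrogram(norm: CountMatrix, groups: pd.Series | np.ndarray
                           ) -> tuple[np.ndarray, list[str]]:
    """Average-linkage dendrogram on 1 - Pearson correlation of centroids.

    Returns ``(scipy linkage matrix, leaf names)``.
    """
    groups = np.asarray(groups)
    cent = _centroids(norm, groups)
    names = list(cent.index)
    if len(names) < 2:
        raise ValueError("need at least two groups for a dendrogram")
    corr = np.corrcoef(cent.to_numpy())
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    return Z, names


def dendrogram_to_newick(Z: np.ndarray, names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    n = len(names)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: names[i] for i in range(n)}
    for k, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[n + k] = h
    return nodes[n + len(Z) - 1] + ";"


# ----------------------------------------------------------------------
# functional panels
# ----------------------------------------------------------------------
def subset_gene_panel(matrix: CountMatrix, prefixes: tuple[str, ...] = (),
                      explicit: list[str] | None = None) -> CountMatrix:
    """Restrict to genes matching any prefix or named explicitly.

    Gene order is preserved.  Matched/unmatched counts are logged; an empty
    match returns an empty submatrix with a warning.
    """
    explicit_set = set(explicit or [])
    mask = np.array([
        g in explicit_set or any(g.startswith(p) for p in prefixes)
        for g in matrix.var.index
    ])
    missing = sorted(explicit_set - set(matrix.var.index))
    logger.info("gene panel: matched %d genes, %d explicit genes absent",
                int(mask.sum()), len(missing))
    if not mask.any():
        logger.warning("gene panel matched no genes")
    return matrix.subset_genes(mask)
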