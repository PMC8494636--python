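"""Embedding, graph clustering, annotation and the neighbour enrichment score.

The clustering route is the standard methylome single-cell recipe: PCA on
posterior levels of highly variable features (50 PCs globally; 30 for the
per-source layer-5 ET re-clustering), a k-nearest-neighbour graph with
Jaccard edge weights over the binary neighbour sets (k = 25 globally, 15
per source), and Louvain modularity clustering (resolution 1.2 globally;
per-source resolutions are configuration).  Clusters are annotated into
subclasses by marker-gene hypomethylation rules, validated by counting
differentially methylated 100-kb bins (DMBs) between cluster pairs, and
under-separated pairs (< 5 DMBs) are merged.

The neighbour enrichment score quantifies, per cell, whether cells of the
same category are nearer in the embedding than cells of other categories:
it is the tie-corrected AUROC of distance over the cell's k same-category
and round(k*r) other-category nearest neighbours, where r is the ratio of
other-category to same-category population sizes.  0.5 is chance, 1 is
perfect local segregation.
"""

from __future__ import annotations

import random as _random
from dataclasses import dataclass
from typing import Sequence

import igraph as ig
import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.decomposition import PCA
from sklearn.metrics import average_precision_score
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MarkerRule",
    "DEFAULT_MARKER_RULES",
    "NeighbourGraph",
    "pca_embed",
    "build_knn_graph",
    "louvain_cluster",
    "annotate_subclasses",
    "dmb_count",
    "dmb_validate_and_merge",
    "neighbour_enrichment_score",
]


def pca_embed(M: np.ndarray, n_pcs: int = 50) -> np.ndarray:
    """Centred PCA embedding; columns ordered by decreasing explained variance."""
    M = np.asarray(M, dtype=float)
    n_pcs = int(n_pcs)
    if n_pcs > min(M.shape):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(n_cells, n_features)={min(M.shape)}")
    if not np.isfinite(M).all():
        raise ValueError("matrix contains non-finite values")
    pca = PCA(n_components=n_pcs, svd_solver="full")
    return pca.fit_transform(M)


@dataclass
class NeighbourGraph:
    neighbours: np.ndarray  # n_cells x k indices of out-neighbours
    edges: list[tuple[int, int, float]]  # undirected, Jaccard-weighted, weight > 0
    n_cells: int
    k: int

    @property
    def connectivity(self) -> sparse.csr_matrix:
        n = self.n_cells
        rows = np.repeat(np.arange(n), self.k)
        cols = self.neighbours.ravel()
        return sparse.csr_matrix((np.ones(n * self.k), (rows, cols)), shape=(n, n))

    def to_igraph(self) -> ig.Graph:
        g = ig.Graph(n=self.n_cells, edges=[(i, j) for i, j, _ in self.edges])
        g.es["weight"] = [w for _, _, w in self.edges]
        return g


def build_knn_graph(embedding: np.ndarray, k: int = 25) -> NeighbourGraph:
    """kNN graph by Euclidean distance; edge weights are Jaccard similarities.

    A_ij = 1 iff j is among i's k nearest neighbours (self excluded, ties
    broken by index order).  The undirected edge (i, j) exists where A_ij or
    A_ji is 1, weighted by |N_i & N_j| / |N_i | N_j|; weight-0 edges are
    dropped.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells, have {n}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    neigh = np.empty((n, k), dtype=np.int64)
    for i in range(n):
        row = idx[i]
        neigh[i] = row[row != i][:k]

    A = sparse.csr_matrix(
        (np.ones(n * k), (np.repeat(np.arange(n), k), neigh.ravel())), shape=(n, n)
    )
    inter = (A @ A.T).tocoo()  # |N_i & N_j|
    candidate = ((A + A.T) > 0).tocoo()
    inter_lookup = {(i, j): v for i, j, v in zip(inter.row, inter.col, inter.data)}
    edges: list[tuple[int, int, float]] = []
    for i, j in zip(candidate.row, candidate.col):
        if i >= j:
            continue
        common = inter_lookup.get((i, j), 0.0)
        if common == 0:
            continue
        union = 2 * k - common
        edges.append((int(i), int(j), float(common / union)))
    return NeighbourGraph(neighbours=neigh, edges=edges, n_cells=n, k=k)


def louvain_cluster(graph: NeighbourGraph, resolution: float = 1.2, seed: int = 0) -> np.ndarray:
    """Louvain (multilevel) modularity clustering; labels contiguous from 0."""
    g = graph.to_igraph()
    rng = _random.Random(seed)
    state = ig.set_random_number_generator
    state(rng)
    try:
        part = g.community_multilevel(weights="weight", resolution=resolution)
    finally:
        state(_random)
    labels = np.asarray(part.membership)
    # relabel contiguously in order of first appearance
    _, labels = np.unique(labels, return_inverse=True)
    return labels


@dataclass(frozen=True)
class MarkerRule:
    """Subclass rule: required hypomethylated (+) and hypermethylated (-) genes."""

    subclass: str
    plus: tuple[str, ...]
    minus: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.plus) & set(self.minus):
            raise ValueError(f"rule {self.subclass}: +/- gene lists overlap")


# gene-body mCH marker rules for mouse cortical subclasses ("+" = hypomethylated
# gene body, the signature of expression)
DEFAULT_MARKER_RULES: tuple[MarkerRule, ...] = (
    MarkerRule("L2/3", plus=("Cux2",), minus=("Rorb",)),
    MarkerRule("L4", plus=("Cux2", "Rorb")),
    MarkerRule("L5 IT", plus=("Rorb",), minus=("Cux2",)),
    MarkerRule("L5 IT", plus=("Deptor",)),
    MarkerRule("L6 IT", plus=("Sulf1",)),
    MarkerRule("L6 IT", plus=("Sulf2",), minus=("Deptor",)),
    MarkerRule("L5 ET", plus=("Vat1l",)),
    MarkerRule("L6 CT", plus=("Foxp2",)),
    MarkerRule("L6b", plus=("Tle4",), minus=("Foxp2",)),
    MarkerRule("NP", plus=("Tshz2",)),
    MarkerRule("CLA", plus=("B3gat2",)),
    MarkerRule("inhibitory", plus=("Slc6a1",)),
)


class AmbiguousAnnotationError(ValueError):
    pass


def annotate_subclasses(
    cluster_gene_mch: pd.DataFrame,
    rules: Sequence[MarkerRule] = DEFAULT_MARKER_RULES,
    margin: float = 0.0,
) -> dict[int | str, str]:
    """Assign each cluster to the unique subclass whose marker rule holds.

    ``cluster_gene_mch`` is clusters x genes mean posterior mCH.  A gene is
    "+" in a cluster iff its value is below the across-cluster median for
    that gene by more than ``margin``, "-" iff above by more than
    ``margin`` (margin 0 reproduces the plain median split).  Clusters
    matching no rule are labelled "unassigned"; rules of two different
    subclasses matching the same cluster raise
    :class:`AmbiguousAnnotationError`.
    """
    needed = {g for r in rules for g in (*r.plus, *r.minus)}
    missing = needed - set(cluster_gene_mch.columns)
    if missing:
        raise KeyError(f"marker genes absent from matrix: {sorted(missing)}")
    med = cluster_gene_mch.median(axis=0)
    plus_sign = cluster_gene_mch.lt(med - margin, axis=1)
    minus_sign = cluster_gene_mch.gt(med + margin, axis=1)

    assignment: dict[int | str, str] = {}
    for cluster in cluster_gene_mch.index:
        matched = [
            r.subclass
            for r in rules
            if all(plus_sign.at[cluster, g] for g in r.plus)
            and all(minus_sign.at[cluster, g] for g in r.minus)
        ]
        distinct = sorted(set(matched))
        if len(distinct) > 1:
            raise AmbiguousAnnotationError(
                f"cluster {cluster!r} matches multiple subclasses: {distinct}"
            )
        assignment[cluster] = distinct[0] if distinct else "unassigned"
    return assignment


def dmb_count(
    levels_a: np.ndarray,
    levels_b: np.ndarray,
    lfc_threshold: float = 1.5,
    fdr: float = 0.01,
    method: str = "wilcoxon",
    auroc_threshold: float = 0.85,
    aupr_threshold: float = 0.6,
) -> int:
    """Number of differentially methylated bins between two cell groups.

    ``wilcoxon`` mode: two-sided rank-sum test per bin, BH correction across
    bins, DMB iff |log fold change of group means| > log(lfc_threshold) and
    FDR < fdr.  ``auroc`` mode: DMB iff per-bin AUROC (taken in the better
    direction) > auroc_threshold and AUPR > aupr_threshold.
    """
    levels_a = np.asarray(levels_a, float)
    levels_b = np.asarray(levels_b, float)
    n_bins = levels_a.shape[1]
    mean_a = levels_a.mean(axis=0)
    mean_b = levels_b.mean(axis=0)
    if method == "wilcoxon":
        res = stats.mannwhitneyu(levels_a, levels_b, axis=0, alternative="two-sided",
                                 method="asymptotic")
        reject, _, _, _ = multipletests(res.pvalue, alpha=fdr, method="fdr_bh")
        with np.errstate(divide="ignore"):
            lfc = np.abs(np.log(mean_a) - np.log(mean_b))
        return int(((lfc > np.log(lfc_threshold)) & reject & (res.pvalue < 1)).sum())
    if method == "auroc":
        n_a, n_b = levels_a.shape[0], levels_b.shape[0]
        u = stats.mannwhitneyu(levels_a, levels_b, axis=0, alternative="two-sided",
                               method="asymptotic").statistic
        auroc = u / (n_a * n_b)
        auroc = np.maximum(auroc, 1.0 - auroc)
        y = np.concatenate([np.ones(n_a), np.zeros(n_b)])
        count = 0
        for j in range(n_bins):
            if auroc[j] <= auroc_threshold:
                continue
            scores = np.concatenate([levels_a[:, j], levels_b[:, j]])
            direction = 1.0 if mean_a[j] >= mean_b[j] else -1.0
            aupr = average_precision_score(y, direction * scores)
            if aupr > aupr_threshold:
                count += 1
        return count
    raise ValueError(f"unknown DMB method {method!r}")


def dmb_validate_and_merge(
    levels: np.ndarray,
    labels: np.ndarray,
    lfc_threshold: float = 1.5,
    fdr: float = 0.01,
    min_dmb: int = 5,
    method: str = "wilcoxon",
) -> tuple[np.ndarray, dict[tuple[int, int], int]]:
    """Merge cluster pairs separated by fewer than ``min_dmb`` DMBs.

    Iterates: count DMBs for every cluster pair (size-1 clusters excluded
    from testing), merge the pair with the fewest DMBs below ``min_dmb``
    (smaller cluster into larger, ties to the lower label), repeat until
    stable.  Returns the merged contiguous labels and the final pairwise
    DMB counts keyed by sorted label pairs.
    """
    labels = np.asarray(labels).copy()
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 clusters")
    while True:
        uniq = np.unique(labels)
        counts: dict[tuple[int, int], int] = {}
        for ai in range(len(uniq)):
            for bi in range(ai + 1, len(uniq)):
                a, b = int(uniq[ai]), int(uniq[bi])
                cells_a = labels == a
                cells_b = labels == b
                if cells_a.sum() < 2 or cells_b.sum() < 2:
                    continue
                counts[(a, b)] = dmb_count(
                    levels[cells_a], levels[cells_b], lfc_threshold, fdr, method
                )
        under = [(n, pair) for pair, n in counts.items() if n < min_dmb]
        if not under:
            old, labels = np.unique(labels, return_inverse=True)
            new_of = {int(o): i for i, o in enumerate(old)}
            counts = {(new_of[a], new_of[b]): n for (a, b), n in counts.items()}
            return labels, counts
        _, (a, b) = min(under)
        # absorb the smaller cluster into the larger
        if (labels == a).sum() >= (labels == b).sum():
            labels[labels == b] = a
        else:
            labels[labels == a] = b
        if len(np.unique(labels)) < 2:
            return np.zeros_like(labels), {}


def neighbour_enrichment_score(
    embedding: np.ndarray,
    labels: Sequence,
    k: int = 25,
) -> tuple[pd.Series, pd.Series]:
    """Per-cell tie-corrected AUROC of embedding distance by category.

    For each cell: take k' = min(k, n_same - 1) nearest same-category
    neighbours and max(1, round(k' * r)) nearest other-category neighbours,
    where r = n_other / n_same over the whole population; the score is the
    probability that a uniformly chosen same-category neighbour is strictly
    closer than a uniformly chosen other-category one, ties counting 1/2.
    Cells in singleton categories receive NaN.  Returns (per-cell scores,
    per-category means).
    """
    embedding = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    n = embedding.shape[0]
    scores = np.full(n, np.nan)
    for i in range(n):
        same_mask = labels == labels[i]
        n_same = int(same_mask.sum())
        n_other = n - n_same
        if n_same < 2 or n_other == 0:
            continue
        d = np.linalg.norm(embedding - embedding[i], axis=1)
        d[i] = np.inf  # exclude self
        r = n_other / n_same
        k_same = min(k, n_same - 1)
        k_other = min(max(1, int(np.floor(k_same * r + 0.5))), n_other)
        d_same = np.sort(d[same_mask])[:k_same]
        d_other = np.sort(d[~same_mask])[:k_other]
        closer = (d_same[:, None] < d_other[None, :]).sum()
        tied = (d_same[:, None] == d_other[None, :]).sum()
        scores[i] = (closer + 0.5 * tied) / (k_same * k_other)
    per_cell = pd.Series(scores, name="neighbour_enrichment")
    per_cat = per_cell.groupby(labels).mean()
    return per_cell, per_cat
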