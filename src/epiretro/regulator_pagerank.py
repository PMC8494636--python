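"""Transcription-factor ranking by restart-PageRank on a DMR-derived network.

Differentially methylated regions (DMRs), expanded 100 bp on both sides,
link an upstream transcription factor (via a motif hit overlapping the
expanded DMR) to a downstream gene (via a region-to-gene assignment).  The
resulting TF -> gene network is weighted by the TF's methylation-predicted
expression in the cluster of interest: the cluster x gene mean mCH matrix
is min-max normalized within each cluster and 1 - N serves as predicted
expression (low gene-body mCH predicts high expression in neurons).

With adjacency A (A_ij = predicted expression of gene i if i is a TF with
an evidence-supported edge to j), the propagation runs on the symmetrized
B = A + A^T, row-normalized into P (dangling genes receive a self-loop and
hold their seed value):

    I_t = (1 - rp) P I_{t-1} + rp I_0

seeded with I_0 = predicted expression, iterated until the L1 change drops
below 1e-5.  Per-TF scores are min-max normalized across clusters for
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegulatoryEvidence",
    "RegNetwork",
    "predicted_expression",
    "build_network",
    "pagerank",
    "rank_regulators",
]

DMR_EXPANSION_BP = 100


def _read_bed3(path, extra: str) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", extra],
        usecols=[0, 1, 2, 3],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, extra: str},
    )


@dataclass
class RegulatoryEvidence:
    """DMR intervals, TF motif hits, and region-to-gene assignments.

    All intervals are 0-based half-open.  ``dmrs`` has columns
    chrom/start/end; ``motif_hits`` adds ``tf``; ``region_genes`` maps DMR
    intervals (matched exactly on chrom/start/end) to ``gene``.
    """

    dmrs: pd.DataFrame
    motif_hits: pd.DataFrame
    region_genes: pd.DataFrame

    @classmethod
    def from_files(cls, dmr_bed, motif_bed, region_gene_tsv) -> "RegulatoryEvidence":
        dmrs = _read_bed3(dmr_bed, "name")[["chrom", "start", "end"]]
        motifs = _read_bed3(motif_bed, "tf")
        region_genes = pd.read_csv(
            region_gene_tsv, sep="\t", header=None, names=["chrom", "start", "end", "gene"]
        )
        return cls(dmrs=dmrs, motif_hits=motifs, region_genes=region_genes)


@dataclass
class RegNetwork:
    genes: list[str]
    adjacency: np.ndarray  # A, directed TF -> gene, weighted by TF predicted expression
    seed_vector: np.ndarray  # I_0, predicted expression of every gene in the cluster
    edge_list: list[tuple[str, str]] = field(default_factory=list)

    @property
    def symmetrized(self) -> np.ndarray:
        return self.adjacency + self.adjacency.T

    @property
    def transition(self) -> np.ndarray:
        """Row-normalized B; dangling rows (zero out-weight) get a self-loop.

        The self-loop makes an unconnected gene a fixed point at its seed
        value (its score neither diffuses away nor decays), so a network
        with no edges returns the seed vector unchanged.
        """
        B = self.symmetrized
        row_sums = B.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(row_sums > 0, B / row_sums, 0.0)
        dangling = np.flatnonzero(row_sums.ravel() == 0)
        P[dangling, dangling] = 1.0
        return P


def predicted_expression(M: pd.DataFrame) -> pd.DataFrame:
    """1 - within-cluster min-max normalization of cluster x gene mean mCH.

    The least methylated gene of a cluster gets predicted expression 1, the
    most methylated 0.  A constant row has no usable contrast and raises.
    """
    arr = M.to_numpy(dtype=float)
    lo = arr.min(axis=1, keepdims=True)
    hi = arr.max(axis=1, keepdims=True)
    if np.any(hi == lo):
        bad = M.index[np.flatnonzero((hi == lo).ravel())].tolist()
        raise ValueError(f"constant methylation row(s), cannot normalize: {bad}")
    N = (arr - lo) / (hi - lo)
    return pd.DataFrame(1.0 - N, index=M.index, columns=M.columns)


def _overlaps(s1: int, e1: int, s2: int, e2: int) -> bool:
    # half-open intervals
    return s1 < e2 and s2 < e1


def build_network(
    evidence: RegulatoryEvidence,
    tf_list: Sequence[str],
    predicted_expr: pd.Series,
    expansion_bp: int = DMR_EXPANSION_BP,
) -> RegNetwork:
    """Construct the TF -> gene network for one cluster.

    An edge TF -> gene exists iff some DMR, expanded ``expansion_bp`` on
    both sides, overlaps at least one motif hit of that TF and is assigned
    to that gene.  A_ij is the TF's predicted expression in the cluster.
    """
    genes = list(predicted_expr.index)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for tf in tf_list:
        if tf not in gene_pos:
            raise KeyError(f"transcription factor {tf!r} absent from the gene universe")
    tf_set = set(tf_list)

    assign = {
        (r.chrom, r.start, r.end): []
        for r in evidence.region_genes.itertuples()
    }
    for r in evidence.region_genes.itertuples():
        assign[(r.chrom, r.start, r.end)].append(r.gene)

    A = np.zeros((len(genes), len(genes)))
    edges: set[tuple[str, str]] = set()
    motifs_by_chrom = {c: g for c, g in evidence.motif_hits.groupby("chrom")}
    for dmr in evidence.dmrs.itertuples():
        lo = max(0, dmr.start - expansion_bp)
        hi = dmr.end + expansion_bp
        targets = assign.get((dmr.chrom, dmr.start, dmr.end), [])
        if not targets:
            continue
        hits = motifs_by_chrom.get(dmr.chrom)
        if hits is None:
            continue
        overlapping = hits[(hits["start"] < hi) & (lo < hits["end"])]
        for tf in overlapping["tf"].unique():
            if tf not in tf_set or tf not in gene_pos:
                continue
            for gene in targets:
                if gene not in gene_pos:
                    continue
                i, j = gene_pos[tf], gene_pos[gene]
                A[i, j] = predicted_expr[tf]
                edges.add((tf, gene))
    seed = predicted_expr.to_numpy(dtype=float)
    return RegNetwork(genes=genes, adjacency=A, seed_vector=seed, edge_list=sorted(edges))


def pagerank(
    network: RegNetwork,
    rp: float = 0.15,
    tol: float = 1e-5,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Restart-PageRank: iterate I = (1 - rp) P I + rp I_0 to L1 tolerance."""
    if not (0.0 < rp <= 1.0):
        raise ValueError(f"restart probability must lie in (0, 1], got {rp}")
    P = network.transition
    I0 = np.asarray(network.seed_vector, dtype=float)
    if not np.isfinite(I0).all():
        raise ValueError("seed vector contains non-finite values")
    I = I0.copy()
    for _ in range(max_iter):
        I_next = (1.0 - rp) * (P @ I) + rp * I0
        if np.abs(I_next - I).sum() < tol:
            return I_next
        I = I_next
    raise RuntimeError(f"PageRank did not converge within {max_iter} iterations")


def rank_regulators(
    scores_per_cluster: pd.DataFrame, tf_list: Sequence[str]
) -> pd.DataFrame:
    """Normalize each TF's PageRank score across clusters (min-max to [0, 1]).

    ``scores_per_cluster`` is clusters x genes.  TFs whose score is
    constant across clusters get 0.5 and are flagged.  Returns a long table
    (cluster, gene, score, norm_score, constant) sorted within cluster by
    normalized score.
    """
    if scores_per_cluster.shape[0] < 2:
        raise ValueError("need at least 2 clusters to normalize across clusters")
    rows = []
    for tf in tf_list:
        col = scores_per_cluster[tf].to_numpy(dtype=float)
        lo, hi = col.min(), col.max()
        constant = hi == lo
        norm = np.full(len(col), 0.5) if constant else (col - lo) / (hi - lo)
        for cluster, s, ns in zip(scores_per_cluster.index, col, norm):
            rows.append(
                {"cluster": cluster, "gene": tf, "score": s, "norm_score": ns,
                 "constant": constant}
            )
    out = pd.DataFrame(rows)
    return out.sort_values(["cluster", "norm_score"], ascending=[True, False]).reset_index(
        drop=True
    )
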