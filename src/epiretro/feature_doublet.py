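"""Highly variable feature selection and simulated-doublet detection.

HVF selection normalizes per-feature dispersion (variance/mean of the
posterior levels) within groups defined by a quantile grid over mean level
and mean coverage, since both drive dispersion of methylation levels; the
top features by within-group z-scored dispersion are kept.

Doublet detection follows the scrublet idea adapted to methylation counts:
simulate doublets by summing the base calls of random cell pairs (twice as
many simulated as observed), recompute posterior levels on the joint set,
embed with PCA on HVFs, and score each observed cell by the fraction of
simulated doublets among its k nearest neighbours.  Cells scoring above
the threshold (default 0.1, strictly) are flagged for removal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .methylome_io import MethylCountMatrix
from .posterior_mch import posterior_matrix

__all__ = ["HvfReport", "DoubletReport", "select_hvf", "doublet_scores"]


@dataclass
class HvfReport:
    table: pd.DataFrame  # mean_level, mean_coverage, dispersion, group, norm_dispersion, selected

    @property
    def selected_mask(self) -> np.ndarray:
        return self.table["selected"].to_numpy()

    @property
    def selected_indices(self) -> np.ndarray:
        order = self.table.loc[self.table["selected"]].sort_values(
            "norm_dispersion", ascending=False
        )
        return order.index.to_numpy()


@dataclass
class DoubletReport:
    table: pd.DataFrame  # cell_id, score, removed
    n_simulated: int
    seed: int

    @property
    def removed_cells(self) -> list[str]:
        return self.table.loc[self.table["removed"], "cell_id"].tolist()

    @property
    def kept_cells(self) -> list[str]:
        return self.table.loc[~self.table["removed"], "cell_id"].tolist()


def _quantile_groups(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-count bin index per value (ties share a bin edge deterministically)."""
    if n_bins <= 1 or len(np.unique(values)) <= 1:
        return np.zeros(len(values), dtype=int)
    quantiles = np.quantile(values, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(quantiles, values, side="right")


def select_hvf(
    M: np.ndarray,
    coverage: np.ndarray,
    n_top: int = 2000,
    n_mean_bins: int = 20,
    n_cov_bins: int = 5,
) -> HvfReport:
    """Rank features by dispersion z-scored within (mean level x coverage) groups."""
    M = np.asarray(M, dtype=float)
    coverage = np.asarray(coverage, dtype=float)
    if M.shape[1] < 2:
        raise ValueError("need at least 2 features")
    mean_level = M.mean(axis=0)
    var_level = M.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean_level > 0, var_level / mean_level, 0.0)

    group = _quantile_groups(mean_level, n_mean_bins) * (n_cov_bins + 1) + _quantile_groups(
        coverage, n_cov_bins
    )
    norm_disp = np.zeros_like(dispersion)
    for gid in np.unique(group):
        members = group == gid
        if members.sum() < 2:
            continue  # singleton groups carry no within-group scale
        d = dispersion[members]
        sd = d.std()
        norm_disp[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    n_select = min(n_top, M.shape[1])
    # stable tie-break on feature order
    order = np.lexsort((np.arange(len(norm_disp)), -norm_disp))
    selected = np.zeros(M.shape[1], dtype=bool)
    selected[order[:n_select]] = True

    table = pd.DataFrame(
        {
            "mean_level": mean_level,
            "mean_coverage": coverage,
            "dispersion": dispersion,
            "group": group,
            "norm_dispersion": norm_disp,
            "selected": selected,
        }
    )
    return HvfReport(table)


def doublet_scores(
    counts: MethylCountMatrix,
    n_pcs: int = 50,
    n_hvf: int = 2000,
    k: int = 50,
    threshold: float = 0.1,
    seed: int = 0,
) -> DoubletReport:
    """Score each observed cell by its simulated-doublet neighbour fraction.

    Simulates 2 x n_observed doublets by summing the counts of uniformly
    chosen distinct cell pairs, computes posterior levels of the joint set,
    selects HVFs, embeds with PCA (centred, unscaled) and takes each
    observed cell's score as the fraction of simulated doublets among its k
    nearest neighbours (self excluded).  Removal requires score strictly
    above the threshold.
    """
    n_obs = counts.n_cells
    if n_obs < 2:
        raise ValueError("need at least 2 observed cells")
    rng = np.random.default_rng(seed)
    n_sim = 2 * n_obs
    if n_obs + n_sim < k + 1:
        raise ValueError(f"need at least {k + 1} cells after augmentation, have {n_obs + n_sim}")

    pairs = np.array([rng.choice(n_obs, size=2, replace=False) for _ in range(n_sim)])
    sim_mc = counts.mc[pairs[:, 0]] + counts.mc[pairs[:, 1]]
    sim_tc = counts.tc[pairs[:, 0]] + counts.tc[pairs[:, 1]]
    joint_mc = np.vstack([counts.mc, sim_mc])
    joint_tc = np.vstack([counts.tc, sim_tc])

    M, _ = posterior_matrix(joint_mc, joint_tc)
    hvf = select_hvf(M, joint_tc.mean(axis=0), n_top=n_hvf)
    X = M[:, hvf.selected_mask]
    n_comp = min(n_pcs, X.shape[0] - 1, X.shape[1])
    emb = PCA(n_components=n_comp, random_state=int(seed) % (2**31)).fit_transform(
        X - X.mean(axis=0)
    )

    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb[:n_obs])
    scores = np.empty(n_obs)
    for i in range(n_obs):
        row = idx[i]
        row = row[row != i][:k]  # self excluded
        scores[i] = (row >= n_obs).mean()

    table = pd.DataFrame(
        {
            "cell_id": counts.cells,
            "score": scores,
            "removed": scores > threshold,
        }
    )
    return DoubletReport(table=table, n_simulated=n_sim, seed=seed)
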