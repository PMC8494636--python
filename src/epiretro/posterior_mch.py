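"""Beta-prior posterior methylation levels.

Sparse single-cell methylome coverage makes raw per-feature mCH ratios
(mc/tc) extremely noisy.  Each cell's per-feature levels are therefore
shrunk toward that cell's own global level with an empirical beta prior
fitted by the method of moments:

    alpha = m * (m(1-m)/v - 1)
    beta  = (1-m) * (m(1-m)/v - 1)

where m and v are the mean and (population) variance of the raw levels
over features with non-zero coverage.  The posterior level of feature j is

    ratio_j = (alpha + mc_j) / (alpha + beta + tc_j)

which is normalized by the cell's global level global = alpha/(alpha+beta)
(= m) to give M_j = ratio_j / global.  Entries above 10 are clipped to 10;
a feature with no coverage has M = 1 exactly (the prior mean equals the
global level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BetaPrior",
    "DegeneratePriorError",
    "fit_beta_prior",
    "posterior_levels",
    "posterior_matrix",
]

M_CLIP = 10.0


class DegeneratePriorError(ValueError):
    """Method-of-moments beta fit is invalid (v >= m(1-m), or no coverage)."""


@dataclass(frozen=True)
class BetaPrior:
    cell_id: str
    m: float
    v: float
    alpha: float
    beta: float

    @property
    def global_level(self) -> float:
        return self.alpha / (self.alpha + self.beta)


def fit_beta_prior(mc: np.ndarray, tc: np.ndarray, cell_id: str = "") -> BetaPrior:
    """Fit the per-cell beta prior from one cell's (mc, tc) over features.

    Only features with tc > 0 enter the moments; v is the population
    variance.  Raises :class:`DegeneratePriorError` when the fit is invalid
    (fewer than 2 covered features, m outside (0,1), or v >= m(1-m)).
    """
    mc = np.asarray(mc, dtype=float)
    tc = np.asarray(tc, dtype=float)
    covered = tc > 0
    if covered.sum() < 2:
        raise DegeneratePriorError(f"cell {cell_id!r}: fewer than 2 covered features")
    levels = mc[covered] / tc[covered]
    m = float(levels.mean())
    v = float(levels.var())  # population variance
    if not (0.0 < m < 1.0):
        raise DegeneratePriorError(f"cell {cell_id!r}: mean level {m} outside (0, 1)")
    if v <= 0.0 or v >= m * (1.0 - m):
        raise DegeneratePriorError(
            f"cell {cell_id!r}: variance {v} incompatible with beta moments (m={m})"
        )
    common = m * (1.0 - m) / v - 1.0
    return BetaPrior(cell_id=cell_id, m=m, v=v, alpha=m * common, beta=(1.0 - m) * common)


def posterior_levels(prior: BetaPrior, mc: np.ndarray, tc: np.ndarray) -> np.ndarray:
    """One cell's normalized posterior levels M, clipped to [0, 10]."""
    mc = np.asarray(mc, dtype=float)
    tc = np.asarray(tc, dtype=float)
    ratio = (prior.alpha + mc) / (prior.alpha + prior.beta + tc)
    m_row = ratio / prior.global_level
    return np.minimum(m_row, M_CLIP)


def posterior_matrix(
    mc: np.ndarray, tc: np.ndarray, cell_ids: list[str] | None = None
) -> tuple[np.ndarray, list[BetaPrior]]:
    """Posterior level matrix M and the per-cell priors for a cells x features matrix."""
    mc = np.asarray(mc)
    tc = np.asarray(tc)
    n_cells = mc.shape[0]
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n_cells)]
    priors: list[BetaPrior] = []
    M = np.empty(mc.shape, dtype=float)
    for i in range(n_cells):
        prior = fit_beta_prior(mc[i], tc[i], cell_id=cell_ids[i])
        priors.append(prior)
        M[i] = posterior_levels(prior, mc[i], tc[i])
    return M, priors
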