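"""Differential methylation and enrichment statistics with replicate-aware models.

Cells from one mouse are correlated, so treating cells as independent
samples overstates power.  Differentially CH-methylated genes (CH-DMGs)
are therefore called with per-gene linear mixed models carrying a mouse
random intercept, fitted by maximum likelihood, with a two-sided Wald test
on the tested coefficient.  Three formula variants are used:

    mCH ~ cluster + sex + global_mCH + (1 | mouse)   (L5 ET cluster pairs)
    mCH ~ target + cluster + sex + global_mCH + (1 | mouse)  (cortical targets)
    mCH ~ target + sex + global_mCH + (1 | mouse)    (ET targets)

Fold changes are ratios of group means with a pseudo-count of 0.1 on each
mean; significance requires |log FC| > log 1.5 (cluster pairs) or
log 1.25 (target pairs) and BH FDR < 0.01.

Projection enrichment in clusters uses the same mixed-model logic on a
binary cluster-membership response (Cluster ~ target + (1 | mouse),
identity link), with (O - E)/E effect sizes from chi-square expected
counts.  The overlap score between two cell groups is the summed minimum
of their row-normalized cluster distributions (1 minus the total-variation
distance).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DMG_THRESHOLDS",
    "ch_dmg_lmm",
    "call_dmgs",
    "naive_ttest",
    "enrichment_test",
    "OverlapMatrix",
    "overlap_score",
]

# (fold-change threshold, FDR threshold) per comparison context
DMG_THRESHOLDS: dict[str, tuple[float, float]] = {
    "l5et_clusters": (1.5, 0.01),
    "targets": (1.25, 0.01),
}

PSEUDOCOUNT = 0.1


def _fit_single_gene(
    data: pd.DataFrame, fixed_terms: list[str]
) -> tuple[float, float, float, bool]:
    """ML mixed-model fit; returns (coef, se, p) for `tested` and convergence."""
    formula = "response ~ tested" + "".join(f" + {t}" for t in fixed_terms)
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("powell", "bfgs"):  # powell is robust near variance boundaries
            try:
                model = smf.mixedlm(formula, data, groups=data["mouse"])
                res = model.fit(reml=False, method=method)
            except Exception:
                continue
            if res.converged and np.isfinite(res.bse.get("tested", np.nan)) \
                    and res.bse.get("tested", 0) > 0:
                break
    if res is None:
        return np.nan, np.nan, np.nan, False
    se_val = res.bse.get("tested", np.nan)
    if not res.converged or not np.isfinite(se_val) or se_val <= 0:
        return np.nan, np.nan, np.nan, False
    coef = float(res.params["tested"])
    se = float(res.bse["tested"])
    z = coef / se
    p = 2.0 * stats.norm.sf(abs(z))
    return coef, se, p, True


def ch_dmg_lmm(
    gene_matrix: np.ndarray,
    design: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "global_mch"),
    group_col: str = "group",
    gene_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-gene mixed-model differential test between two cell groups.

    ``gene_matrix`` is cells x genes posterior mCH; ``design`` needs the
    binary ``group_col``, ``mouse``, and any requested covariates among
    {"cluster", "sex", "global_mch"}.  Returns one row per gene with the
    tested coefficient, Wald statistics, BH FDR (non-convergent genes are
    excluded from correction and carry NaN) and the pseudo-counted fold
    change (group 1 mean + 0.1) / (group 0 mean + 0.1).
    """
    gene_matrix = np.asarray(gene_matrix, dtype=float)
    levels = np.unique(design[group_col])
    if len(levels) != 2:
        raise ValueError(f"tested effect must be binary, found {list(levels)}")
    if design["mouse"].nunique() < 2:
        raise ValueError("need at least 2 mice for a mouse random intercept")
    tested = (design[group_col] == levels[1]).astype(float).to_numpy()

    fixed_terms = []
    for cov in covariates:
        if cov in ("cluster", "sex"):
            fixed_terms.append(f"C({cov})")
        else:
            fixed_terms.append(cov)

    n_genes = gene_matrix.shape[1]
    if gene_names is None:
        gene_names = [f"gene_{j}" for j in range(n_genes)]

    base = pd.DataFrame({"tested": tested, "mouse": design["mouse"].to_numpy()})
    for cov in covariates:
        base[cov] = design[cov].to_numpy()

    rows = []
    for j in range(n_genes):
        data = base.copy()
        data["response"] = gene_matrix[:, j]
        coef, se, p, converged = _fit_single_gene(data, fixed_terms)
        mean0 = gene_matrix[tested == 0, j].mean()
        mean1 = gene_matrix[tested == 1, j].mean()
        fc = (mean1 + PSEUDOCOUNT) / (mean0 + PSEUDOCOUNT)
        rows.append(
            {
                "gene": gene_names[j],
                "coef": coef,
                "se": se,
                "z": coef / se if converged else np.nan,
                "p_value": p,
                "fold_change": fc,
                "converged": converged,
            }
        )
    results = pd.DataFrame(rows)
    results["fdr"] = np.nan
    ok = results["converged"].to_numpy()
    if ok.any():
        _, fdr, _, _ = multipletests(results.loc[ok, "p_value"], method="fdr_bh")
        results.loc[ok, "fdr"] = fdr
    return results


def call_dmgs(results: pd.DataFrame, context: str = "l5et_clusters") -> pd.DataFrame:
    """Significant genes: |log FC| above the context threshold and FDR < 0.01."""
    fc_thr, fdr_thr = DMG_THRESHOLDS[context]
    lfc = np.abs(np.log(results["fold_change"].to_numpy()))
    sig = (lfc > np.log(fc_thr)) & (results["fdr"].to_numpy() < fdr_thr)
    out = results.copy()
    out["significant"] = sig & results["converged"].to_numpy()
    return out.loc[out["significant"]]


def naive_ttest(gene_matrix: np.ndarray, design: pd.DataFrame, group_col: str = "group") -> np.ndarray:
    """Per-gene Welch t-test treating cells as independent (for comparison only)."""
    gene_matrix = np.asarray(gene_matrix, dtype=float)
    levels = np.unique(design[group_col])
    a = gene_matrix[(design[group_col] == levels[0]).to_numpy()]
    b = gene_matrix[(design[group_col] == levels[1]).to_numpy()]
    return stats.ttest_ind(a, b, equal_var=False, axis=0).pvalue


def enrichment_test(table: pd.DataFrame) -> pd.DataFrame:
    """Projection-target enrichment per cluster with mouse-aware mixed models.

    ``table`` needs columns cluster, target, mouse (cells of one source).
    For every (cluster, target) pair a linear mixed model
    indicator(cluster) ~ indicator(target) + (1 | mouse) is fitted by ML;
    the Wald p on the target coefficient is BH-corrected across all tested
    pairs.  (O - E)/E comes from the contingency table with chi-square
    expected counts E = row_total * col_total / grand_total.
    """
    contingency = pd.crosstab(table["cluster"], table["target"])
    O = contingency.to_numpy(dtype=float)
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    E = row @ col / O.sum()

    rows = []
    for ci, cluster in enumerate(contingency.index):
        in_cluster = (table["cluster"] == cluster).astype(float).to_numpy()
        for ti, target in enumerate(contingency.columns):
            if O[ci, ti] == 0 and row[ci, 0] == 0:
                continue
            data = pd.DataFrame(
                {
                    "response": in_cluster,
                    "tested": (table["target"] == target).astype(float).to_numpy(),
                    "mouse": table["mouse"].to_numpy(),
                }
            )
            coef, se, p, converged = _fit_single_gene(data, [])
            rows.append(
                {
                    "cluster": cluster,
                    "target": target,
                    "observed": int(O[ci, ti]),
                    "expected": E[ci, ti],
                    "rel_enrichment": (O[ci, ti] - E[ci, ti]) / E[ci, ti],
                    "coef": coef,
                    "p_value": p,
                    "converged": converged,
                }
            )
    results = pd.DataFrame(rows)
    results["fdr"] = np.nan
    ok = results["converged"].to_numpy()
    if ok.any():
        _, fdr, _, _ = multipletests(results.loc[ok, "p_value"], method="fdr_bh")
        results.loc[ok, "fdr"] = fdr
    return results


@dataclass
class OverlapMatrix:
    scores: pd.DataFrame  # group x group
    counts: pd.DataFrame  # group x cluster C
    distributions: pd.DataFrame  # row-normalized D


def overlap_score(labels_group: Sequence, labels_cluster: Sequence) -> OverlapMatrix:
    """Summed minimum of two groups' cluster distributions (1 - TV distance)."""
    C = pd.crosstab(pd.Series(labels_group, name="group"), pd.Series(labels_cluster, name="cluster"))
    totals = C.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("every group must be non-empty")
    D = C.div(totals, axis=0)
    groups = D.index
    mat = np.zeros((len(groups), len(groups)))
    Dv = D.to_numpy()
    for i in range(len(groups)):
        for j in range(len(groups)):
            mat[i, j] = np.minimum(Dv[i], Dv[j]).sum()
    scores = pd.DataFrame(mat, index=groups, columns=groups)
    return OverlapMatrix(scores=scores, counts=C, distributions=D)
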