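"""FANS-run level filtering of unreliable projection-target assignments.

Retrograde labelling artefacts (permissive sorting gates on weak
projections, injection tracts through overlying cortex) show up as whole
sorting runs whose subclass composition resembles an unbiased sample
rather than the expected on-target enrichment.  Each run is assessed by
fold enrichment of on- vs off-target subclass counts relative to an
unbiased reference composition, and a one-sided exact binomial
goodness-of-fit test:

    fold = (O_on * E_off) / (O_off * E_on)
    p    = Pr(X >= O_on),  X ~ Binomial(n = O_on + O_off, p = E_on / (E_on + E_off))

with Benjamini-Hochberg correction across runs within a target class.
ET-target runs require fold >= 5 and FDR < 0.01; IT-target runs fold >= 3
and FDR < 0.05.  Cells in failing runs keep their source but their
projection target becomes "unknown".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "RunAssessment",
    "ON_OFF_SUBCLASSES",
    "CLASS_THRESHOLDS",
    "count_on_off",
    "assess_run",
    "apply_run_filter",
]

# on-/off-target subclass maps per injection class; subclasses in neither
# set are ignored in the counts
ON_OFF_SUBCLASSES: dict[str, dict[str, frozenset[str]]] = {
    "ET": {
        "on": frozenset({"L5 ET"}),
        "off": frozenset({"L2/3", "L4", "L5 IT", "L6 IT", "inhibitory"}),
    },
    "IT": {
        "on": frozenset({"L2/3", "L4", "L5 IT", "L6 IT"}),
        "off": frozenset({"L6 CT", "inhibitory"}),
    },
}

# (fold enrichment, FDR) pass thresholds per target class
CLASS_THRESHOLDS: dict[str, tuple[float, float]] = {"ET": (5.0, 0.01), "IT": (3.0, 0.05)}


@dataclass
class RunAssessment:
    fans_run: str
    target_class: str
    o_on: int
    o_off: int
    e_on: float
    e_off: float
    fold_enrichment: float = field(default=np.nan)
    p_value: float = field(default=np.nan)
    fdr: float = field(default=np.nan)
    passed: bool = False


def count_on_off(
    subclasses: pd.Series | list[str],
    target_class: str,
    subclass_map: dict[str, dict[str, frozenset[str]]] = ON_OFF_SUBCLASSES,
    strict: bool = False,
) -> tuple[int, int]:
    """Count a run's cells in on- and off-target subclasses for its class."""
    if target_class not in subclass_map:
        raise KeyError(f"unknown target class {target_class!r}")
    on = subclass_map[target_class]["on"]
    off = subclass_map[target_class]["off"]
    o_on = o_off = 0
    for s in subclasses:
        if s in on:
            o_on += 1
        elif s in off:
            o_off += 1
        elif strict:
            raise ValueError(f"subclass {s!r} in neither on- nor off-target set")
    return o_on, o_off


def assess_run(o_on: int, o_off: int, e_on: float, e_off: float) -> tuple[float, float]:
    """Fold enrichment and one-sided exact binomial p for one run.

    fold is +inf when O_off = 0; the p-value is Pr(X >= O_on) under
    X ~ Binomial(O_on + O_off, E_on / (E_on + E_off)), by exact summation.
    An empty run (n = 0) gets fold 0 and p 1.
    """
    if e_on <= 0:
        raise ValueError("reference on-target count E_on must be positive")
    n = o_on + o_off
    if n == 0:
        return 0.0, 1.0
    fold = np.inf if o_off == 0 else (o_on * e_off) / (o_off * e_on)
    p_ref = e_on / (e_on + e_off)
    # Pr(X >= o_on) = survival function at o_on - 1
    p_value = float(stats.binom.sf(o_on - 1, n, p_ref))
    return float(fold), p_value


def apply_run_filter(
    runs: pd.DataFrame,
    target_class: str,
    reference_composition: dict[str, float],
    subclass_map: dict[str, dict[str, frozenset[str]]] = ON_OFF_SUBCLASSES,
    thresholds: dict[str, tuple[float, float]] = CLASS_THRESHOLDS,
) -> list[RunAssessment]:
    """Assess every FANS run of one target class and flag the passing ones.

    ``runs`` needs columns fans_run and subclass (one row per cell).
    ``reference_composition`` gives unbiased subclass proportions (or
    counts) from which E_on / E_off are computed.  BH correction is applied
    across the runs of the class; a run passes iff fold >= fold_threshold
    AND fdr < fdr_threshold.
    """
    fold_thr, fdr_thr = thresholds[target_class]
    on = subclass_map[target_class]["on"]
    off = subclass_map[target_class]["off"]
    e_on = sum(v for s, v in reference_composition.items() if s in on)
    e_off = sum(v for s, v in reference_composition.items() if s in off)

    assessments: list[RunAssessment] = []
    for run_id, grp in runs.groupby("fans_run", sort=True):
        o_on, o_off = count_on_off(grp["subclass"], target_class, subclass_map)
        fold, p = assess_run(o_on, o_off, e_on, e_off) if o_on + o_off > 0 else (0.0, 1.0)
        assessments.append(
            RunAssessment(str(run_id), target_class, o_on, o_off, e_on, e_off, fold, p)
        )
    if not assessments:
        return assessments
    pvals = np.array([a.p_value for a in assessments])
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    for a, q in zip(assessments, fdrs):
        a.fdr = float(q)
        a.passed = (a.fold_enrichment >= fold_thr) and (a.fdr < fdr_thr)
    return assessments


def relabel_failed_runs(table: pd.DataFrame, assessments: list[RunAssessment]) -> pd.DataFrame:
    """Set target = "unknown" for cells in runs that failed the filter."""
    failed = {a.fans_run for a in assessments if not a.passed}
    out = table.copy()
    out.loc[out["fans_run"].isin(failed), "target"] = "unknown"
    return out
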