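"""Synthetic single-cell methylome data with known ground truth.

Emulates the statistical structure of retrograde-labelled snmC-seq data:
cells belong to clusters nested in subclasses; each cluster has a
per-feature true mCH rate profile; cells carry a global-level scaling
factor and a mouse random intercept (mice are biological replicates, two
per sex); projection groups (source, target) draw their cells from
subclass mixtures; FANS sorting runs can be contaminated with cells from
an unbiased subclass distribution; doublets are sums of two parent cells'
base calls.

For feature j of cell i (cluster c, mouse m):

    tc_ij ~ NegativeBinomial(mean, dispersion)
    mc_ij ~ Binomial(tc_ij, clip(rate_cj * g_i + u_m + effects, 0, 1))

where g_i ~ Normal(1, sd) is the cell's global scaling and u_m the mouse
intercept on the fraction scale.  True mCH rates are on the scale of
normalized neuronal gene-body/bin mCH rather than absolute genome-wide
levels, so that planted differences of 0.1-0.3 are resolvable at
desk-scale coverage.

Everything is deterministic given the design seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .methylome_io import AllcRecord, FeatureSet, MethylCountMatrix, write_allc

__all__ = [
    "Effect",
    "SimulationDesign",
    "GroundTruth",
    "DEFAULT_UNBIASED_COMPOSITION",
    "simulate_cells",
    "inject_doublets",
    "simulate_fans_runs",
    "write_synthetic_allc",
    "simulate_lmm_dataset",
]

# subclass composition of an unbiased (no projection enrichment) cortical sort
DEFAULT_UNBIASED_COMPOSITION: dict[str, float] = {
    "L2/3": 0.30,
    "L5 IT": 0.30,
    "L5 ET": 0.15,
    "inhibitory": 0.25,
}

# per-(target) subclass mixtures: ET injections label mostly L5 ET neurons,
# IT (cortical) injections label IT subclasses
_ET_MIXTURE = {"L5 ET": 0.90, "L5 IT": 0.04, "L2/3": 0.03, "inhibitory": 0.03}
_IT_MIXTURE = {"L2/3": 0.45, "L5 IT": 0.45, "L5 ET": 0.05, "inhibitory": 0.05}

# marker-gene true rates per cluster (L2/3, L5 IT, L5 ET, inhibitory):
# hypomethylated (low) in the subclass the marker identifies
_MARKER_RATES = {
    "Cux2": (0.10, 0.30, 0.30, 0.30),
    "Rorb": (0.45, 0.10, 0.30, 0.30),
    "Deptor": (0.30, 0.10, 0.30, 0.30),
    "Vat1l": (0.30, 0.30, 0.10, 0.30),
    "Slc6a1": (0.30, 0.30, 0.30, 0.10),
}


@dataclass(frozen=True)
class Effect:
    """Additive rate shift for cells matching metadata values, at given features.

    ``where`` maps CellTable columns to required values (AND).  ``features``
    are integer indices into the combined feature axis.  Used to plant
    projection-target signal shared or private across sources.
    """

    where: Mapping[str, str]
    features: tuple[int, ...]
    delta: float


@dataclass
class SimulationDesign:
    n_cells: int = 600
    n_bins: int = 3000
    n_genes: int = 1000
    n_clusters: int = 4
    subclass_of_cluster: tuple[str, ...] = ("L2/3", "L5 IT", "L5 ET", "inhibitory")
    bin_base_rate: float = 0.40
    bin_marker_fraction: float = 0.12  # exclusive marker bins per cluster
    bin_marker_delta: float = 0.30  # marker bins are hypomethylated by this much
    gene_base_rate: float = 0.30
    coverage_mean: float = 300.0
    coverage_dispersion: float = 20.0  # NB size parameter; larger = less overdispersed
    global_level_sd: float = 0.08
    mice: tuple[tuple[str, str], ...] = (("m1", "M"), ("m2", "M"), ("f1", "F"), ("f2", "F"))
    sigma_mouse: float = 0.02
    sources: tuple[str, ...] = ("MOp", "ACA")
    targets: tuple[tuple[str, str], ...] = (("VISp", "IT"), ("TH", "ET"))  # (name, class)
    runs_per_group: int = 3
    contaminated_runs_per_group: int = 0
    contamination_level: float = 0.9
    unbiased_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UNBIASED_COMPOSITION)
    )
    qc_fail_fraction: float = 0.05
    doublet_rate: float = 0.0
    extra_effects: tuple[Effect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.subclass_of_cluster) != self.n_clusters:
            raise ValueError("subclass_of_cluster must name one subclass per cluster")
        if not (0.0 <= self.contamination_level <= 1.0):
            raise ValueError("contamination_level must lie in [0, 1]")
        if self.sigma_mouse < 0:
            raise ValueError("sigma_mouse must be >= 0")

    def target_mixture(self, target_class: str) -> dict[str, float]:
        mix = _ET_MIXTURE if target_class == "ET" else _IT_MIXTURE
        # restrict to subclasses present in this design and renormalize
        present = set(self.subclass_of_cluster)
        mix = {s: w for s, w in mix.items() if s in present}
        total = sum(mix.values())
        return {s: w / total for s, w in mix.items()}


@dataclass
class GroundTruth:
    """Per-cell latent labels and per-feature differential annotation."""

    cells: pd.DataFrame  # cell_id, cluster, subclass, doublet, contaminant
    features: pd.DataFrame  # feature_id, cluster (marker-of), delta
    contaminated_runs: set[str] = field(default_factory=set)


def _build_features(design: SimulationDesign) -> FeatureSet:
    rows = []
    for b in range(design.n_bins):
        start = b * 100_000
        rows.append(("chr1", start, start + 100_000, f"chr1:{start}-{start + 100_000}", "bin100kb"))
    marker_names = [g for g in _MARKER_RATES if design.n_clusters == 4]
    for g in range(design.n_genes):
        start = g * 10_000
        name = marker_names[g] if g < len(marker_names) else f"gene_{g:04d}"
        rows.append(("chr2", start, start + 5_000, name, "gene"))
    return FeatureSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "feature_id", "kind"]))


def _cluster_rates(design: SimulationDesign, rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """True rate profile per cluster over bins + genes, plus marker-bin truth."""
    n_feat = design.n_bins + design.n_genes
    rates = np.full((design.n_clusters, n_feat), design.bin_base_rate)
    rates[:, design.n_bins:] = design.gene_base_rate

    n_marker = int(round(design.bin_marker_fraction * design.n_bins))
    perm = rng.permutation(design.n_bins)
    truth_rows = []
    for c in range(design.n_clusters):
        marker_bins = perm[c * n_marker : (c + 1) * n_marker]
        rates[c, marker_bins] = design.bin_base_rate - design.bin_marker_delta
        for j in marker_bins:
            truth_rows.append((int(j), c, -design.bin_marker_delta))

    if design.n_clusters == 4:
        for g, name in enumerate(_MARKER_RATES):
            rates[:, design.n_bins + g] = _MARKER_RATES[name]
    feature_truth = pd.DataFrame(truth_rows, columns=["feature_index", "cluster", "delta"])
    return rates, feature_truth


def _draw_subclass(rng: np.random.Generator, mixture: Mapping[str, float]) -> str:
    names = list(mixture)
    probs = np.array([mixture[s] for s in names])
    return names[rng.choice(len(names), p=probs / probs.sum())]


def simulate_cells(
    design: SimulationDesign,
) -> tuple[MethylCountMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the full cells x (bins + genes) count matrix with metadata.

    Returns the count matrix, the observable cell table (cell_id, source,
    target, target_class, mouse, sex, fans_run, n_nonclonal_reads,
    mccc_level) and the ground truth (cluster, subclass, contaminant flags,
    contaminated runs, marker-bin table).
    """
    rng = np.random.default_rng(design.seed)
    features = _build_features(design)
    rates, feature_truth = _cluster_rates(design, rng)
    feature_truth["feature_id"] = features.feature_ids[feature_truth["feature_index"]]

    cluster_of_subclass: dict[str, list[int]] = {}
    for c, s in enumerate(design.subclass_of_cluster):
        cluster_of_subclass.setdefault(s, []).append(c)

    groups = [(src, tgt, cls) for src in design.sources for tgt, cls in design.targets]
    per_group = design.n_cells // len(groups)
    if per_group == 0:
        raise ValueError(
            f"n_cells={design.n_cells} too small for {len(groups)} (source, target) groups"
        )
    mice = list(design.mice)
    mouse_u = {m: rng.normal(0.0, design.sigma_mouse) for m, _ in mice}

    rows = []
    for src, tgt, cls in groups:
        for k in range(per_group):
            mouse, sex = mice[rng.integers(len(mice))]
            rows.append(
                {
                    "source": src,
                    "target": tgt,
                    "target_class": cls,
                    "mouse": mouse,
                    "sex": sex,
                }
            )
    table = pd.DataFrame(rows)
    table["cell_id"] = [f"cell_{i:04d}" for i in range(len(table))]

    # per-run assignment with planted contamination, then subclass draws
    table, contaminated_runs, contaminant = _assign_runs_and_subclasses(table, design, rng)
    cluster = np.array(
        [cluster_of_subclass[s][rng.integers(len(cluster_of_subclass[s]))] for s in table["subclass"]]
    )

    n_cells, n_feat = len(table), len(features)
    g = np.clip(rng.normal(1.0, design.global_level_sd, size=n_cells), 0.5, 1.5)
    u = np.array([mouse_u[m] for m in table["mouse"]])

    p = rates[cluster] * g[:, None] + u[:, None]
    for eff in design.extra_effects:
        mask = np.ones(n_cells, dtype=bool)
        for col, val in eff.where.items():
            mask &= (table[col] == val).to_numpy()
        idx = np.asarray(eff.features, dtype=int)
        p[np.ix_(mask, idx)] += eff.delta
    p = np.clip(p, 0.0, 1.0)

    # NB(mean, size) as gamma-poisson
    size = design.coverage_dispersion
    lam = rng.gamma(shape=size, scale=design.coverage_mean / size, size=(n_cells, n_feat))
    tc = rng.poisson(lam)
    mc = rng.binomial(tc, p)

    # QC covariates: most cells pass; a designed fraction violates one rule
    reads = np.maximum(rng.normal(1.5e6, 3e5, size=n_cells), 6e5).astype(np.int64)
    mccc = np.clip(rng.beta(2.0, 500.0, size=n_cells), 0.0, 0.02)
    fail = rng.random(n_cells) < design.qc_fail_fraction
    fail_mode = rng.random(n_cells) < 0.5
    reads[fail & fail_mode] = rng.integers(1e5, 499_999, size=int((fail & fail_mode).sum()))
    mccc[fail & ~fail_mode] = rng.uniform(0.011, 0.05, size=int((fail & ~fail_mode).sum()))

    table["n_nonclonal_reads"] = reads
    table["mccc_level"] = mccc
    cells = table["cell_id"].tolist()
    matrix = MethylCountMatrix(cells, features, mc, tc, context="CH")

    truth_cells = pd.DataFrame(
        {
            "cell_id": cells,
            "cluster": cluster,
            "subclass": table["subclass"].to_numpy(),
            "doublet": False,
            "contaminant": contaminant,
            "global_scale": g,
            "mouse_intercept": u,
        }
    )
    truth = GroundTruth(
        cells=truth_cells,
        features=feature_truth[["feature_id", "cluster", "delta"]],
        contaminated_runs=contaminated_runs,
    )
    table = table[
        ["cell_id", "source", "target", "target_class", "mouse", "sex", "fans_run",
         "n_nonclonal_reads", "mccc_level", "subclass"]
    ].copy()

    if design.doublet_rate > 0:
        matrix, table, truth = inject_doublets(
            matrix, table, design.doublet_rate, seed=int(rng.integers(2**31)), truth=truth
        )
    return matrix, table, truth


def _assign_runs_and_subclasses(
    table: pd.DataFrame, design: SimulationDesign, rng: np.random.Generator
) -> tuple[pd.DataFrame, set[str], np.ndarray]:
    """Split each (source, target) group into FANS runs; draw subclasses.

    The first ``contaminated_runs_per_group`` runs of each group are
    contaminated: each of their cells is drawn from the unbiased subclass
    composition with probability ``contamination_level`` instead of the
    on-target mixture.
    """
    table = table.copy()
    subclass = np.empty(len(table), dtype=object)
    fans_run = np.empty(len(table), dtype=object)
    contaminant = np.zeros(len(table), dtype=bool)
    contaminated_runs: set[str] = set()

    for (src, tgt, cls), idx in table.groupby(["source", "target", "target_class"]).groups.items():
        idx = np.asarray(idx)
        mixture = design.target_mixture(cls)
        run_of_cell = rng.integers(design.runs_per_group, size=len(idx))
        for r in range(design.runs_per_group):
            run_id = f"{src}-{tgt}-run{r}"
            run_cells = idx[run_of_cell == r]
            is_contaminated_run = r < design.contaminated_runs_per_group
            if is_contaminated_run:
                contaminated_runs.add(run_id)
            for i in run_cells:
                fans_run[i] = run_id
                if is_contaminated_run and rng.random() < design.contamination_level:
                    subclass[i] = _draw_subclass(rng, design.unbiased_composition)
                    contaminant[i] = True
                else:
                    subclass[i] = _draw_subclass(rng, mixture)
    table["subclass"] = subclass
    table["fans_run"] = fans_run
    return table, contaminated_runs, contaminant


def simulate_fans_runs(
    table: pd.DataFrame, design: SimulationDesign, seed: int | None = None
) -> tuple[pd.DataFrame, set[str]]:
    """Re-assign FANS runs and plant contamination on an existing cell table.

    Cells in contaminated runs have their subclass redrawn from the unbiased
    composition with probability ``contamination_level``; counts drawn from
    the returned table afterwards are then consistent with the new labels.
    Returns the updated table (columns ``fans_run``, ``subclass``,
    ``contaminant``) and the set of contaminated run ids.
    """
    if "subclass" not in table.columns:
        raise ValueError("table must carry subclass labels")
    rng = np.random.default_rng(design.seed if seed is None else seed)
    table = table.copy()
    contaminant = np.zeros(len(table), dtype=bool)
    fans_run = np.empty(len(table), dtype=object)
    subclass = table["subclass"].to_numpy(copy=True)
    contaminated_runs: set[str] = set()

    pos_of = {lab: i for i, lab in enumerate(table.index)}
    for (src, tgt), idx in table.groupby(["source", "target"]).groups.items():
        idx = np.asarray([pos_of[i] for i in idx])
        run_of_cell = rng.integers(design.runs_per_group, size=len(idx))
        for r in range(design.runs_per_group):
            run_id = f"{src}-{tgt}-run{r}"
            run_cells = idx[run_of_cell == r]
            contaminated = r < design.contaminated_runs_per_group
            if contaminated:
                contaminated_runs.add(run_id)
            for i in run_cells:
                fans_run[i] = run_id
                if contaminated and rng.random() < design.contamination_level:
                    subclass[i] = _draw_subclass(rng, design.unbiased_composition)
                    contaminant[i] = True
    table["fans_run"] = fans_run
    table["subclass"] = subclass
    table["contaminant"] = contaminant
    return table, contaminated_runs


def inject_doublets(
    matrix: MethylCountMatrix,
    table: pd.DataFrame,
    rate: float,
    seed: int,
    truth: GroundTruth | None = None,
) -> tuple[MethylCountMatrix, pd.DataFrame, GroundTruth]:
    """Append doublets: elementwise sums of mc and tc of two distinct parents.

    ``rate`` is the doublet fraction of the augmented population:
    n_doublets = round(rate / (1 - rate) * n_cells).
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError(f"doublet rate must lie in [0, 1), got {rate}")
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells to form doublets")
    rng = np.random.default_rng(seed)
    n = matrix.n_cells
    n_doublets = int(round(rate / (1.0 - rate) * n))
    if n_doublets == 0:
        if truth is None:
            truth = GroundTruth(cells=pd.DataFrame({"cell_id": matrix.cells, "doublet": False}),
                                features=pd.DataFrame())
        return matrix, table, truth

    mc_rows, tc_rows, new_rows, truth_rows = [], [], [], []
    for d in range(n_doublets):
        a, b = rng.choice(n, size=2, replace=False)
        mc_rows.append(matrix.mc[a] + matrix.mc[b])
        tc_rows.append(matrix.tc[a] + matrix.tc[b])
        cid = f"doublet_{d:04d}"
        parent = table.iloc[a].to_dict()
        parent["cell_id"] = cid
        new_rows.append(parent)
        truth_rows.append({"cell_id": cid, "doublet": True,
                           "parent_a": matrix.cells[a], "parent_b": matrix.cells[b]})

    mc = np.vstack([matrix.mc, np.array(mc_rows)])
    tc = np.vstack([matrix.tc, np.array(tc_rows)])
    cells = matrix.cells + [r["cell_id"] for r in new_rows]
    out_matrix = MethylCountMatrix(cells, matrix.features, mc, tc, matrix.context)
    out_table = pd.concat([table, pd.DataFrame(new_rows)], ignore_index=True)

    if truth is None:
        truth = GroundTruth(
            cells=pd.DataFrame({"cell_id": matrix.cells, "doublet": False}),
            features=pd.DataFrame(),
        )
    doublet_cells = pd.DataFrame(truth_rows)
    truth_cells = pd.concat([truth.cells, doublet_cells], ignore_index=True)
    truth_cells["doublet"] = truth_cells["doublet"].fillna(False).astype(bool)
    return out_matrix, out_table, GroundTruth(
        cells=truth_cells, features=truth.features, contaminated_runs=truth.contaminated_runs
    )


def write_synthetic_allc(
    matrix: MethylCountMatrix,
    out_dir: str | os.PathLike,
    sites_per_feature: int = 1,
    seed: int = 0,
) -> dict[str, str]:
    """Render the count matrix as per-cell ALLC files (CH context sites).

    Each feature becomes ``sites_per_feature`` sites at distinct positions
    inside its interval; site total calls split the feature's tc
    multinomially and methylated calls follow a multivariate hypergeometric
    draw, so per-feature sums reproduce the matrix exactly on
    re-aggregation.  Deterministic given the seed.
    """
    if sites_per_feature < 1:
        raise ValueError("sites_per_feature must be >= 1")
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(seed)
    tbl = matrix.features.table
    k = sites_per_feature
    # distinct positions inside each interval (1-based)
    positions = np.stack(
        [np.linspace(s, e - 1, num=k).astype(np.int64) + 1 for s, e in zip(tbl["start"], tbl["end"])]
    )
    paths: dict[str, str] = {}
    for i, cell in enumerate(matrix.cells):
        records = []
        for j in range(matrix.n_features):
            tc_total = int(matrix.tc[i, j])
            mc_total = int(matrix.mc[i, j])
            if k == 1:
                covs = np.array([tc_total])
            else:
                covs = rng.multinomial(tc_total, np.full(k, 1.0 / k))
            mcs = rng.multivariate_hypergeometric(covs, mc_total) if tc_total else np.zeros(k, int)
            chrom = tbl.at[j, "chrom"]
            for site in range(k):
                records.append(
                    AllcRecord(
                        chrom=chrom, pos=int(positions[j, site]), strand="+",
                        context="CAT", mc=int(mcs[site]), cov=int(covs[site]),
                    )
                )
        path = os.path.join(out_dir, f"{cell}.allc.tsv")
        write_allc(records, path)
        paths[cell] = path
    return paths


def simulate_lmm_dataset(
    n_genes: int = 50,
    n_per_group: int = 150,
    delta: float = 0.15,
    baseline: float = 0.5,
    sigma_mouse: float = 0.02,
    sigma_cell: float = 0.05,
    n_mice: int = 4,
    differential_fraction: float = 1.0,
    confound_by_mouse: bool = False,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray]:
    """Cells x genes response matrix for differential-methylation model checks.

    Response = baseline + delta * group (differential genes only) + mouse
    intercept + cell noise.  Each mouse contributes cells to both groups
    unless ``confound_by_mouse`` is set, in which case the two groups come
    from disjoint mice (the group effect is then indistinguishable from the
    mouse effect, and delta is NOT added — any signal is spurious).
    Returns (response, design table, per-gene differential flag).
    """
    rng = np.random.default_rng(seed)
    n_cells = 2 * n_per_group
    group = np.repeat([0, 1], n_per_group)
    if confound_by_mouse:
        half = n_mice // 2
        mouse = np.concatenate([
            rng.integers(0, half, size=n_per_group),
            rng.integers(half, n_mice, size=n_per_group),
        ])
    else:
        mouse = rng.integers(0, n_mice, size=n_cells)
    sex = np.where(mouse % 2 == 0, "M", "F")
    global_mch = rng.normal(1.0, 0.05, size=n_cells)

    is_diff = rng.random(n_genes) < (0.0 if confound_by_mouse else differential_fraction)
    response = np.empty((n_cells, n_genes))
    for gidx in range(n_genes):
        u = rng.normal(0.0, sigma_mouse, size=n_mice)
        mu = baseline + (delta * group if is_diff[gidx] else 0.0)
        response[:, gidx] = mu + u[mouse] + rng.normal(0.0, sigma_cell, size=n_cells)

    design = pd.DataFrame(
        {
            "cell_id": [f"cell_{i:04d}" for i in range(n_cells)],
            "group": np.where(group == 1, "B", "A"),
            "mouse": [f"mouse_{m}" for m in mouse],
            "sex": sex,
            "global_mch": global_mch,
        }
    )
    return response, design, is_diff
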