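# epiretro

Analysis toolkit for single-nucleus DNA methylomes of retrogradely labelled
cortical projection neurons (epi-retro-seq-style snmC-seq data), built around
ground-truthed synthetic data.

Projection neurons are labelled by a retrograde tracer injected in a target
region, sorted by FANS, and profiled with single-nucleus bisulfite
sequencing. The resulting per-cell ALLC tables are sparse and noisy, and the
questions — do neurons projecting to different targets differ epigenetically,
which genes are differentially methylated, which transcription factors drive
cluster identity — require statistics that respect replicate (mouse)
structure and sorting artefacts. This package implements that analysis chain
for methods work and benchmarking at desk scale:

- **`methylome_io`** — ALLC parsing/writing, aggregation of sites into
  cells × (100-kb bin | gene body) methylated/total base-call matrices per
  context (CH / CG / CCC), cell QC (≥ 500,000 non-clonal reads, mCCC
  non-conversion ≤ 1%) and coverage-based feature filters (> 100 calls in
  > 95% of cells for bins, > 80% for genes, autosomes only).
- **`posterior_mch`** — per-cell beta-prior shrinkage of mCH levels. With
  method-of-moments parameters α = m(m(1−m)/v − 1), β = (1−m)(m(1−m)/v − 1),
  the posterior level of feature *j* is ratio_j = (α + mc_j)/(α + β + tc_j),
  normalized by the cell's global level α/(α+β) and clipped at 10. A feature
  with no coverage gets exactly 1.
- **`feature_doublet`** — highly variable feature selection with dispersion
  z-scored inside a mean × coverage quantile grid, and scrublet-style doublet
  scores from 2n simulated summed-count doublets, PCA, and a k = 50
  nearest-neighbour classifier.
- **`clustering_scores`** — PCA, Jaccard-weighted kNN graph, Louvain
  clustering, marker-gene subclass annotation (Cux2, Rorb, Deptor, Vat1l,
  Slc6a1, ...), validation of cluster pairs by differentially methylated bins
  (merge below 5 DMBs), and the per-cell neighbour enrichment score (the
  tie-corrected AUROC of embedding distance for same- vs other-category
  neighbours: 0.5 = chance, 1 = perfect segregation).
- **`projection_filter`** — FANS-run-level confidence filter for
  projection-target assignment: fold enrichment (O_on·E_off)/(O_off·E_on)
  against an unbiased reference composition, one-sided exact binomial
  goodness-of-fit test, BH correction; thresholds (5, 0.01) for ET targets
  and (3, 0.05) for IT targets.
- **`target_prediction`** — pairwise separability of projection groups by
  AUROC of L2-regularized logistic regression, with subclass-balanced
  upsampling, computational (repeated 50/50) or biological (by sex) splits,
  and cross-source / cross-layer transfer.
- **`differential_stats`** — CH-DMG calling with per-gene linear mixed models
  (`mCH ~ tested + covariates + (1 | mouse)`, ML fit, two-sided Wald test,
  BH FDR, pseudo-counted fold change), projection-enrichment tests in
  clusters (`Cluster ~ target + (1 | mouse)`, (O−E)/E effect sizes), and the
  overlap score Σ_k min(D_ik, D_jk).
- **`regulator_pagerank`** — TF → gene networks from DMRs (±100 bp) that
  overlap TF motif hits and carry region→gene assignments, seeded with
  methylation-predicted expression (1 − min-max mCH), ranked by restart
  PageRank I_t = (1−rp)·P·I_{t−1} + rp·I₀.
- **`synthetic_data`** — the ground-truth generator: negative-binomial
  coverage, binomial methylated calls at cluster-specific rates with
  per-cell global scaling and mouse random intercepts, projection-to-subclass
  mixtures, contaminated FANS runs, summed-count doublets, and ALLC export.
- **`pipeline_cli`** — the `epiretro` command line and `run_pipeline`, which
  chain the stages on a working directory with one YAML config and a JSON
  manifest.

## Worked example

```python
import numpy as np
from epiretro import SimulationDesign, simulate_cells
from epiretro.posterior_mch import posterior_matrix
from epiretro.feature_doublet import select_hvf
from epiretro.clustering_scores import (pca_embed, build_knn_graph, louvain_cluster,
                                        dmb_validate_and_merge, neighbour_enrichment_score)
from sklearn.metrics import adjusted_rand_score

design = SimulationDesign(seed=0)           # 600 cells, 3,000 bins, 4 mice
matrix, cells, truth = simulate_cells(design)
bins = matrix.select_kind("bin100kb")
M, priors = posterior_matrix(bins.mc, bins.tc, bins.cells)
print(f"cells: {matrix.n_cells}, bins: {bins.n_features}, "
      f"mean global mCH: {np.mean([p.global_level for p in priors]):.3f}")

hvf = select_hvf(M, bins.tc.mean(axis=0), n_top=2000)
emb = pca_embed(M[:, hvf.selected_mask], n_pcs=50)
labels = louvain_cluster(build_knn_graph(emb, k=25), resolution=1.2, seed=0)
labels, _ = dmb_validate_and_merge(M[:, hvf.selected_mask], labels)
print(f"clusters: {len(np.unique(labels))}, "
      f"ARI vs truth: {adjusted_rand_score(truth.cells['cluster'], labels):.3f}")

scores, per_cat = neighbour_enrichment_score(emb, truth.cells["subclass"], k=25)
print(per_cat.round(3).to_string())
```

prints

```
cells: 600, bins: 3000, mean global mCH: 0.380
clusters: 4, ARI vs truth: 1.000
L2/3          1.0
L5 ET         1.0
L5 IT         1.0
inhibitory    1.0
```

The mean global mCH is each cell's beta-prior mean over bins; Louvain
over-partitions at resolution 1.2 and the DMB merge rule restores the four
planted subclasses exactly (adjusted Rand index 1.0); neighbour enrichment
scores of 1.0 say that every cell's subclass neighbours are strictly closer
in the embedding than cells of other subclasses.

The same run from a shell:

```sh
epiretro run-all --seed 0 --out out/     # or stage by stage:
epiretro simulate --seed 0 --out out/ && epiretro qc --out out/ && ...
```

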