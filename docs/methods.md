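# Methods

## The data model

snmC-seq yields, per nucleus, a table of cytosine sites with methylated
(`mc`) and total (`cov`) base calls. Sites are classified by their 3-mer
context: CG (second base G), CH (second base A/C/T; includes CCC), and CCC,
whose genome-wide level estimates the bisulfite non-conversion rate. Counts
are aggregated into cells × feature matrices over 100-kb genomic bins and
gene bodies (full annotated span, start to end; the annotation does not
distinguish exonic from intronic cytosines). ALLC positions are 1-based;
feature intervals are 0-based half-open, so a site at position `pos` falls
in features containing `pos − 1`. For CG aggregation the two strands of a
CpG are combined before counting. Sex chromosomes are excluded from all
count matrices by default, so male and female mice act as biological
replicates; a flag re-includes them.

Cell QC keeps cells with at least 500,000 non-clonal reads and an mCCC
level of at most 1% (boundary values kept — removal is by strict
inequality). Features are kept when covered by more than 100 base calls in
more than 95% of cells (bins) or 80% (genes), both strict.

## Posterior mCH

Raw per-feature levels mc/tc are unusable at single-cell coverage, so each
cell gets an empirical beta prior fitted by the method of moments from the
mean m and population variance v of its raw levels over covered (tc > 0)
features of the analysis feature set (i.e. after the coverage filter):

    alpha = m (m(1−m)/v − 1),   beta = (1−m)(m(1−m)/v − 1)

The posterior level of feature j, (alpha + mc_j)/(alpha + beta + tc_j), is
divided by the cell's global level alpha/(alpha+beta) = m, and entries above
10 are clipped to 10. Zero-coverage features sit exactly at 1 (the prior
mean), so missingness is neutral rather than zero. Degenerate moment fits
(v ≥ m(1−m), fewer than 2 covered features) raise instead of clamping:
they indicate pathological input. The population (not sample) variance is
used; at thousands of features the difference is far below test tolerances.

## Highly variable features and doublets

Both the mean level and the mean coverage of a feature drive the dispersion
(variance/mean) of its posterior levels, so features are grouped on a
quantile (equal-count) grid — 20 mean-level × 5 coverage bins — and the
dispersion is z-scored within each group; the top 2,000 features by
normalized dispersion are kept. Quantile bins avoid empty groups under
skewed coverage; groups of size one get z = 0. The dispersion definition
(variance/mean) is a convention of this package.

Doublets are detected by simulating twice as many doublets as observed
cells (each the element-wise sum of the mc and tc of two uniformly chosen
distinct cells), recomputing posterior levels on the joint set, selecting
HVFs, embedding with centred (not variance-scaled — posterior levels share
a ratio scale) PCA into 50 components, and scoring each observed cell by
the fraction of simulated doublets among its 50 nearest neighbours, self
excluded. The score is the raw simulated-neighbour fraction, without a
Bayesian ratio correction; removal requires a score strictly above 0.1.

That fixed cut presumes a landscape of many clusters: doublets whose
parents share a cluster are statistically indistinguishable from singlets,
so the singlet score baseline is roughly 2s/(1+2s) for cluster share s.
With tens of clusters (s ≲ 0.05) the baseline sits below 0.1; in this
package's 4-subclass demo designs it is ~0.4–0.55, and the threshold would
remove nearly everything even though planted doublets rank cleanly above
singlet cores (median doublet score ≈ 0.8 vs singlet 90th percentile ≈
0.6). The demo pipeline therefore disables doublet *removal* by default
(`run_doublet_stage`); scores, the 2n simulation rule, k = 50 and the
strict-0.1 semantics are implemented and tested as properties.

## Clustering, annotation and cluster validation

The global recipe: PCA (50 components) on posterior levels of the 2,000
HVFs, a kNN graph by Euclidean distance (k = 25, self excluded, ties broken
by cell order), undirected edges weighted by the Jaccard similarity of the
binary neighbour sets (zero-weight edges dropped — similarity, not
distance, because modularity optimization needs affinity weights), and
Louvain clustering at resolution 1.2, run through igraph's multilevel
implementation seeded via Python's RNG. The per-source layer-5 ET
configuration uses 30 components, k = 15, and per-source resolutions
(MOp/AI/AUD/RSP 1.6, SSp/PTLp 2.0, VISp 1.0, ACA 2.5) stored in the
default config.

Clusters are merged into subclasses by marker-gene rules on cluster-mean
gene-body mCH: a gene is "+" (hypomethylated, hence expressed) in a cluster
when its mean sits below the across-cluster median for that gene, "−" when
above; a cluster is assigned to the unique rule whose conditions all hold
(Cux2+Rorb− → L2/3, Cux2+Rorb+ → L4, Cux2−Rorb+ or Deptor+ → L5 IT,
Sulf1+ or Sulf2+Deptor− → L6 IT, Vat1l+ → L5 ET, Foxp2+ → L6 CT,
Tle4+Foxp2− → L6b, Tshz2+ → NP, B3gat2+ → CLA, Slc6a1+ → inhibitory).
The median split stands in for expert judgement; an optional margin (the
pipeline uses 0.05) keeps near-median sampling noise from producing
spurious signs. Rules from two different subclasses matching one cluster
raise an explicit ambiguity error.

Cluster separations are validated by differentially methylated bins: per
cluster pair and bin, a two-sided Wilcoxon rank-sum test on posterior
levels, BH correction across bins, DMB when |log fold change of cluster
means| > log 1.5 and FDR < 0.01 (an alternative mode uses AUROC > 0.85 and
AUPR > 0.6, evaluated in the better direction). Pairs with fewer than 5
DMBs are merged — smaller cluster into larger, a convention — repeating
until stable. On the synthetic designs this also repairs Louvain's habit of
splitting one well-separated cluster at resolution 1.2.

### Neighbour enrichment score

For a cell in category c: with n_same cells in c (including the cell) and
n_other elsewhere, take k′ = min(25, n_same − 1) nearest same-category
cells and min(max(1, round(k′·r)), n_other) nearest other-category cells,
r = n_other/n_same. The score is the probability that a uniformly chosen
same-category neighbour is strictly closer than a uniformly chosen
other-category neighbour, ties counting ½ — the Mann–Whitney U statistic
normalized by the number of pairs. Chance is 0.5, perfect segregation 1.
Cells in singleton categories are excluded (NaN). Rounding of 25r is to
nearest with a floor of 1; both choices matter only for tiny categories.

## FANS-run projection filter

Sorting artefacts contaminate whole runs, so the filter acts per FANS run,
never per cell. Per run, cells are counted into on- and off-target
subclasses (ET injections: on = L5 ET, off = IT subclasses + inhibitory;
IT injections: on = IT subclasses, off = L6 CT + inhibitory; others
ignored) and compared with an unbiased reference composition E:

    fold = (O_on·E_off)/(O_off·E_on)     (+inf when O_off = 0)
    p    = Pr(X ≥ O_on), X ~ Binomial(O_on+O_off, E_on/(E_on+E_off))

BH correction runs within each target class (the thresholds differ by
class, so pooling would mix decision rules). A run passes when fold ≥ 5
and FDR < 0.01 (ET) or fold ≥ 3 and FDR < 0.05 (IT); cells of failing runs
keep their source but get target "unknown". The reference composition is a
configurable table; the synthetic design supplies its own.

## Differential methylation and enrichment

Cells within a mouse are correlated; treating them as independent inflates
power. CH-DMGs are therefore called per gene with a linear mixed model
carrying a mouse random intercept, fitted by maximum likelihood (ML rather
than REML so Wald statistics are comparable across the three formula
variants, which differ in fixed effects):

- L5 ET cluster pairs: mCH ~ cluster + sex + global_mCH + (1 | mouse)
- cortical targets per source: mCH ~ target + cluster + sex + global_mCH + (1 | mouse)
- ET targets per source: mCH ~ target + sex + global_mCH + (1 | mouse)

Optimization uses Powell's method with a BFGS fallback; near the variance
boundary (mouse variance ≈ 0) line-search optimizers routinely fail or
return zero standard errors, while Powell converges and the boundary fit is
legitimate. Non-convergent genes are flagged, counted, and excluded from BH
correction rather than assigned p = 1. The two-sided Wald p on the tested
coefficient is BH-corrected within each group pair. Fold change is the
ratio of group means of posterior mCH (the response variable, for
consistency) with 0.1 added to each mean; significance needs |log FC| >
log 1.5 (cluster pairs) or log 1.25 (target pairs) and FDR < 0.01.

Projection enrichment per cluster uses the same machinery on a binary
response: indicator(cell ∈ cluster) ~ indicator(target) + (1 | mouse) with
an identity link, as the formula is written — not a logistic model — with
BH within source and (O−E)/E effect sizes from chi-square expected counts.

The overlap score between two cell groups is Σ_k min(D_ik, D_jk) over
their row-normalized cluster distributions, i.e. 1 − total-variation
distance: 1 for identical distributions, 0 for disjoint support.

## Transcription-factor ranking

DMRs (consumed as input, ±100 bp expansion, half-open overlap) connect a TF
(motif hit overlapping the expanded DMR) to a gene (region→gene
assignment, matched on the exact DMR interval). A_ij carries the TF's
predicted expression in the cluster of interest — 1 minus the within-
cluster min-max normalization of cluster-mean gene mCH, per cluster as the
formulas imply. Propagation runs on B = A + Aᵀ row-normalized into P, with
I_t = (1−rp)·P·I_{t−1} + rp·I₀ from I₀ = predicted expression until the L1
change drops below 1e-5 (the convergence criterion is interpreted as the
successive-iterate L1 difference). Dangling rows receive a self-loop, so an
unconnected gene holds its seed value and an empty network returns I₀
exactly; the alternative — zero rows, which decay dangling scores to
rp·I₀ — was rejected because diffusion through absent edges should be a
no-op, not a sink. rp defaults to 0.15, the customary restart probability;
it is surfaced as a required config key. For ranking, each TF's PageRank
score is min-max normalized across clusters (constant TFs get 0.5,
flagged). For rp > 0 the iteration is a contraction, so a 10⁴-iteration
cap is a guard, not a tuning parameter.

## The synthetic generator

`simulate_cells` emulates the statistical structure the analysis assumes,
not genome sequence or read-level data. For cell i (cluster c, mouse m) and
feature j:

    tc_ij ~ NegativeBinomial(mean = 300, size = 20)      (gamma–Poisson)
    mc_ij ~ Binomial(tc_ij, clip(rate_cj·g_i + u_m + planted effects, 0, 1))

with g_i ~ Normal(1, 0.08) clipped to [0.5, 1.5] (per-cell global-level
variation) and u_m ~ Normal(0, 0.02) (mouse intercepts on the fraction
scale, matching the additive LMM). Default scale: 600 cells, 3,000 bins,
1,000 genes, 4 clusters/subclasses (L2/3, L5 IT, L5 ET, inhibitory), 4 mice
(two per sex), two sources × one IT and one ET target, three FANS runs per
(source, target). Bins sit at rate 0.40 with each cluster hypomethylated by
0.30 at an exclusive 12% of bins; genes sit at 0.30 with marker genes
(Cux2, Rorb, Deptor, Vat1l, Slc6a1) hypomethylated at 0.10 in their
subclass. These rates are on the scale of normalized neuronal bin/gene mCH,
chosen so planted differences of 0.1–0.3 are resolvable at desk-scale
coverage; absolute genome-wide neuronal mCH (~3%) is not emulated, so
passing tests demonstrate the statistical machinery, not absolute-scale
behaviour on real data. Also not emulated: genomic autocorrelation, CG-DMR
fine structure, batch effects beyond mouse and FANS run.

ET-target runs draw subclasses from {L5 ET 0.90, L5 IT 0.04, L2/3 0.03,
inhibitory 0.03}; IT-target runs from {L2/3 0.45, L5 IT 0.45, L5 ET 0.05,
inhibitory 0.05}; the unbiased reference is {0.30, 0.30, 0.15, 0.25}.
Contaminated runs redraw each cell's subclass from the unbiased composition
with the configured probability, before counts are drawn, so counts remain
consistent with labels. Doublets are exact element-wise parent sums.
A 5% fraction of cells is planted to violate one QC rule so the QC stage
is exercised. ALLC export renders each feature as k sites (multinomial
coverage split, multivariate-hypergeometric methylated-call split), so
re-aggregation reproduces the matrix exactly. Everything is deterministic
given the design seed; pipeline stages derive their seeds from the global
seed by a fixed affine map.

`simulate_lmm_dataset` generates the differential-testing scenarios
directly on the response scale (baseline 0.5, cell noise SD 0.05, mouse SD
0.02, Δ = 0.15, 150 cells/group over 4 mice by default). The
mouse-confounded scenario — groups from disjoint mice, no true effect —
uses 20 mice and mouse SD 0.05: with 4 mice the variance component is
estimated from ~2 degrees of freedom and routinely collapses to zero,
making any test on it meaningless; ~10 mice per group make it estimable, so
the mixed model's protection (versus a naive per-cell t-test) is visible.

## Problem sizes and numerical choices

Simulations default to 600 cells × 3,000 bins — the full pipeline runs in
well under a minute on one CPU — and tests use 200–600 cells. Tolerances:
beta-prior and posterior oracles at 1e-12 (pure arithmetic); stochastic
recovery tests at 3 standard errors of their own sampling distribution;
PageRank at its stated 1e-5. Tie-breaks are deterministic everywhere (cell
or feature order). The enrichment test's null behaviour is calibrated: on
null (cluster, target) pairs its p-values are uniform, so at FDR 0.05 about
5% of runs with one effective null test show a flag — that is the designed
error rate of the procedure, not a defect.

## Known limitations

- The doublet threshold 0.1 is meaningful only in many-cluster regimes (see
  above); the module reports scores regardless.
- Wald tests with few mice are anti-conservative (the z reference behaves
  like a small-df t); the package does not apply a Satterthwaite-style
  correction because the method specifies plain Wald tests.
- The marker-rule median split can be ambiguous on real data with many
  clusters; the ambiguity error and the margin parameter surface this
  rather than resolving it silently.
- The run filter models contamination only at run level; residual
  contamination inside passing runs is out of scope.
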