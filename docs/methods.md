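# Methods

`stcelldyn` analyses imaging-based spatial transcriptomics of mouse brain
under a 2×2 design: *Oprm1* genotype (AA wild-type vs GG variant) crossed
with treatment (saline, SAL, vs chronic morphine, MOR). Each cell carries a
count vector over a ~1,000-plex probe panel (plus negative-control probes),
spatial coordinates, a field of view (FOV), and hierarchical brain-region
labels (depths 3/5/7 of a CCF-style ontology, supplied as metadata). This
note documents the statistical procedures, the choices made where the
design was genuinely open, and what the synthetic testbed does and does not
establish.

## Quality control

*Probe level.* Negative-control probes are screened with an iterative
two-sided Grubbs test on per-probe total counts (α = 0.01): the most
extreme value is tested against the critical value
((n−1)/√n)·√(t²/(n−2+t²)), t = t(α/2n, n−2), removed if significant, and
the test repeats. Retained negatives define the background. Targets are
removed if their total count falls below the 50th percentile of the
retained-negative totals, or if a one-sided Poisson exceedance test of the
target total against the mean negative total gives P > 0.01. The
"background-corrected detection P-value" is not a uniquely defined
quantity; the Poisson exceedance test is our concrete, replaceable choice,
and whether the background cut uses per-probe totals (our choice,
configurable) or per-cell means is equally open.

*Cell level.* Cells are retained with ≥5 total transcripts, ≤10% of counts
on negative probes, a total-count/detected-gene ratio strictly >1, and a
segmentation area that is not a Grubbs outlier (α = 0.01). Boundary
inequalities are deliberately strict/non-strict exactly as listed.

*FOV level.* Two stages: a run-level gate (mean counts/cell ≥ 100, mean
negative counts/cell ≤ 1.0, ≥ 500 cells) and a pipeline-level gate (mean
transcripts/cell ≥ 10). Since 500-cell FOVs are not meaningful at the
scale of the synthetic fixtures, the run-level cell minimum is multiplied
by a configurable `cell_scale` (recorded in the QC report); all other
thresholds are used verbatim.

*Normalization.* LogNormalize: x = ln(1 + 10,000·count/cell_total).
Natural log throughout, except log2 where the analysis is defined on
log2CPM (identity calling) or log2 fold changes. A pre-clustering
secondary filter removes cells below the 5th percentile (linear
interpolation convention) of total counts or detected genes.

## Clustering and label propagation

The AA-SAL group (genetically wild-type, opioid-naive) is the clustering
reference. Genes are standardized (clipped at ±10), the top 100 principal
components are fitted, and components with |Pearson r| > 0.7 against the
technical bias vector (log2 total counts per cell) are dropped — the
absolute value is used because anti-correlated components are equally
technical. The retained count is derived from the data, never hard-coded.
A shared-nearest-neighbor graph (exact kNN, k = 50, Jaccard weights,
edges ≤ 1/15 pruned) feeds Louvain community detection; "auto" resolution
scans a grid (0.4–2.0, step 0.2) and keeps the partition with the highest
modularity, which is a concrete reading of an otherwise unspecified
automatic rule. Remaining cells are projected with the reference loadings
(no re-fit, so that all cells share one space) and labeled by a
200-tree random forest; reference cells are never relabeled. For
visualization, up to 1,000 cells per cluster enter a t-SNE on the retained
components. Every stochastic step takes an explicit seed; with n ≤ 5,000
the whole path is deterministic.

## Identity rules and annotation

A cell is "high" for a gene when log2(CPM+1) > 3 on raw counts (CPM uses a
+1 pseudocount inside the log). A two-component Gaussian mixture fitted to
the gene's log2CPM distribution is reported as a bimodality diagnostic
(component means, posterior crossover) but the fixed consensus threshold
decides the call. An identity rule is a conjunction of alternative-gene
groups (e.g. dopaminergic: {Slc6a3 or Slc18a2} and {Th} and {Ddc};
astrocytes: one structural of {Gfap, Aldoc, S100b} and one functional of
{Slc1a3, Aqp4, Agt}); the full table ships as editable JSON
(`stcelldyn/data/rules.json`). A cluster receives every identity passed by
strictly more than 30% of its cells; the primary identity is the largest
fraction with lexicographic tie-breaking (ties are not otherwise defined).
Clusters passing nothing are "Other".

Marker-based cluster QC uses one-vs-rest Wilcoxon markers: high-confidence
markers need adjusted P < 0.01 and q_diff ≥ 0.7, where q_diff is the
detection-fraction difference (fraction expressing inside − outside the
cluster; the quantity is not otherwise defined, and this reading is
flagged here deliberately). The DE score is Σ −log10(P_adj) over
high-confidence markers with each gene's contribution capped at 300 to
avoid infinities from underflowed P-values; retention needs ≥ 8 markers
and DE score ≥ 150. Reference-set validation uses the overlap score
|markers ∩ set|/|markers| over user-supplied GMT collections. The 4-level
hierarchy is: neuronal/non-neuronal → primary identity → identity ×
dominant depth-3 region → cluster id. Manual blinded refinement is
replaced by a machine-readable override applied last.

## Differential expression and disproportionality

All two-group tests are Wilcoxon rank-sum (exact null for tiny tie-free
groups, tie-corrected normal approximation otherwise) with
Benjamini–Hochberg adjustment across tested genes. BH is used for *all*
comparisons, including cluster markers, for internal consistency (a
deliberate divergence from tools that default to Bonferroni there). Fold
changes are computed on the de-logged expression scale:
log2((mean(eˣ−1)+ε)/(…+ε)) with ε = 1/scale_factor, which keeps measured
log2FC on the same scale as planted count-level effects. Cluster DE
defaults: min.pct 0.25, log2FC threshold 0.1, clusters ≥ 50 cells,
upregulated-only for marker lists. Inter-regional DE subsamples 500 cells
per depth-5 region (seeded) and applies adjusted P < 0.01, |log2FC| > 1.5;
a gene is region-specific when it passes in exactly one region.

The disproportionality statistic: per cell type, valid DEGs are those with
nonzero mean expression in the type (types with a valid fraction < 0.25
excluded; the fraction is configurable because no number is canonical);
the composite score is the unweighted mean over valid DEGs of the gene's
mean normalized expression (a |log2FC|-weighted variant is available via
`weighted=True`, since both readings are defensible); composites are
z-scored across types with the population (n) convention; a type is
flagged when |z| > 1.6449 (the two-sided 90% normal quantile, reported
rounded to 1.64) *and* its mean |log2FC| over valid DEGs exceeds 1.
Flagging on 8 types with a forced mean-0/sd-1 z-vector has a null rate
near the nominal 10%, which is why the null-calibration test tolerates up
to 15%.

Composition dynamics: per (region-depth-7, cell type, genotype) with all
four groups ≥ 50 cells, pct_change = 100·(n_MOR − n_SAL)/n_SAL. "Min–max
normalization followed by log transformation" is order-ambiguous for
negative values; we apply a symmetric log first (sign(x)·log1p(|x|/100))
and then min–max to [−1, 1], recording the order. Circle sizes are
log1p(n_SAL) clipped to the 5th–95th percentile range. Shannon H
(natural log) summarizes a type's spread over regions per treatment
state; the Gini coefficient summarizes cell-type inequality within a
region.

## Enrichment

The per-cell score for term T is a weighted mean difference on
gene-standardized expression, score(c,T) = Σ_{g∈T∩DEG} w_g z_cg / Σ w_g −
mean_{g∈DEG} z_cg with w = |log2FC| — a deterministic alternative to a
running-sum GSEA statistic, isolated in one function so a KS-style variant
can be swapped in. Verdicts use per-term percentile cutoffs (default
90/10; no canonical values exist). The background is the DEG list itself,
matching the way the scores are built from DEG rankings. Regional
over-representation is hypergeometric with BH across terms; the composite
−log10(q)·mean(log2FC of hits) is differenced between genotypes (AA −
GG) to give the bias. GO-slim roll-up ranks terms by frequency across
region/module/group combinations, then minimum FDR, keeps the top 60 and
attaches every parent from a flat child→parent map (no OBO parsing).

## Co-expression modules

Module detection runs on region × group mean-expression rows (regions
with < 100 cells per group excluded), pooled across all four groups — a
pooled fit rather than a multi-set consensus, following the pooled
region×gene wording of the workflow this reimplements. Correlation is
biweight midcorrelation (Tukey weights, c = 9·MAD; genes with zero MAD
fall back to mean/SD weights), unsigned adjacency |bicor|^β with β chosen
by the scale-free criterion (signed R² of the binned log-log degree
regression > 0.8 over powers 1–20, default 8 when nothing qualifies —
uniform planted modules are intentionally not scale-free, so the fallback
path is routine on synthetic data). The topological overlap matrix is the
standard neighborhood-sharing form TOM_ij = (Σ_u a_iu a_uj + a_ij)/
(min(k_i,k_j) + 1 − a_ij).

Tree cutting: average-linkage clustering on 1−TOM followed by a
height-quantile cut (deepSplit 0–4 maps to quantiles 0.99–0.95 of the
maximal merge height; deeper split ⇒ lower cut ⇒ more branches), branches
below minModuleSize = 20 to grey, then iterative merging of modules whose
eigengene dissimilarity (1−cor) is below mergeCutHeight = 0.10. This is a
simplified dynamic cut (no PAM stage, consistent with PAM disabled in the
reference parameters); over-split branches are reassembled by the merge
step, which is the behavior the planted-module tests exercise. Eigengenes
are unit-norm first principal components of the standardized module
expression, sign-oriented to correlate positively with the module mean.
Module–trait association is Pearson r with a two-sided t-approximate P.
Module enrichment for effect gene sets (externally supplied risk genes;
DEG sets from paired region-wise t-tests at FDR < 0.05, |log2FC| > 0.25)
is a one-sided Fisher exact test, −log10 p capped at 10 and normalized to
[0,1] within each effect. Prioritization ranks |AA-treatment −
GG-treatment| enrichment difference and per-effect maxima, with
lexicographic tie-breaking.

## Differential networks and hubs

For each module and genotype, region×region Pearson matrices over module
genes are computed per condition on inner-joined regions; Δ = r_MOR −
r_SAL is normalized by max|Δ| (before truncation) and the top 200 edges
by |normalized Δ| are kept (lexicographic tie-break). The construction is
antisymmetric under condition swap by definition, which the tests assert
exactly.

Gene-level hubs use mutual-information networks per condition:
equal-frequency discretization into ⌈√n⌉ bins, plug-in MI (nats), a
permutation significance threshold (default 100 permutations, α = 0.05 —
added because a raw MI matrix is a complete graph on which degree is
meaningless; parameters exposed and logged), then data-processing-
inequality pruning (the weakest edge of each triangle is removed when
weaker than both others beyond a tolerance, default 0). Degree is the
count of retained edges; Δhub = degree_MOR − degree_SAL; the top three
hubs by |Δhub| (ties: higher MOR degree, then name) seed a subnetwork of
MOR-neighbors ranked by MI, truncated to 25 nodes. Region-specific
modules: eigengenes averaged per region, z-scored across regions, flagged
at |z| > 1.5, with "exactly one region exceeds" recorded separately.

## Synthetic data: what it emulates and what it does not

The generator draws gamma-Poisson counts: gene baselines from a
log-normal, library sizes log-normal (median 500, matching per-cell totals
of imaging-based panels at desk scale), dispersion α = 0.1
(var = μ + αμ²), and negative probes Poisson at 2% of the mean real-probe
rate — giving ~0.2 negative counts/cell, comfortably inside the sub-0.54
regime reported for real runs. Eight cell types × 200 cells per group
(three more groups mirror the reference), 40 markers per type at +2 log2
in-type and −2 log2 elsewhere: canonical rule genes are given a high
baseline (3× the median gene) because real marker transcripts are among
the most abundant in their type, and near-silent outside. Cell types have
a home depth-7 region holding 50% of their cells; each FOV maps to one
depth-7 region; areas are Gaussian.

Treatment effects are planted as +1.5 log2 on 12 genes in MOR cells of
genotype AA, with those genes additionally elevated (+2 log2) in one
focus type to create the hyper-responsive population the
disproportionality statistic is designed to find. Four 30-gene modules are
planted with per-region scores and per-gene loadings; the loadings come in
antithetic ± pairs summing to zero and the modulation is linear,
(1 + loading·score), so module mass is exactly conserved per cell —
otherwise the per-cell normalization leaks a shared region-dependent
factor that spuriously couples modules. Region scores are mutually
orthogonal Hadamard sign patterns (constant magnitude), so even-order
distortions of the concave measurement scale are constant across regions
and cannot couple modules either; with an incompatible region count the
generator falls back to QR-orthogonalized Gaussian patterns. Rewiring
flips one module's score at one region in MOR cells, inverting that
region's module correlations — note this flips *all* pairs involving that
region, so recovery tests check membership of the flipped region in the
top edge rather than a unique pair.

Not emulated: segmentation errors and doublets, spatial autocorrelation
within regions, batch/slide effects, transcript-level coordinates,
dropout beyond what gamma-Poisson sampling produces, and realistic
gene–gene correlation outside the planted modules. Passing recovery tests
therefore shows the estimators are correct and well-calibrated under the
stated generative model, not that they are robust to those artifacts.

## Problem sizes and numerics

Default analyses run 6,400 cells × 1,020 probes; recovery checks use five
generator seeds; null calibration uses twenty. These sizes were chosen so
each planted structure is recovered with a comfortable margin while the
whole suite stays interactive. Degenerate inputs are handled explicitly:
zero-variance genes are excluded before correlation (grey in module
detection), zero-total cells are rejected by name at normalization,
composite-score vectors with zero spread give all-zero z (nothing
flagged), constant traits give NaN correlations, and Grubbs with n < 3
returns nothing with a warning. Percentiles use linear interpolation;
z-scores use the population convention; the disproportionality cutoff is
stored at 1.6449 and reported as 1.64.
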