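# Methods

This note documents the models, conventions and numerical choices behind
`tisig`, in the spirit of a statistical methods appendix: what each
component computes, which decisions were genuinely open, and what the
synthetic validation does and does not demonstrate.

## Quality control and normalization

QC operates on raw gene × cell UMI matrices in a fixed order: genes
detected (count > 0) in fewer than `min_cells_per_gene = 3` cells are
removed first; cells are then filtered on (a) detected non-spike-in genes,
kept when `100 ≤ detected ≤ 7000` (the removal rules are strict "less
than"/"more than", so the bounds themselves are retained), (b)
mitochondrial count fraction ≤ 0.25 and (c) ERCC spike-in fraction ≤ 0.90,
both computed over all counts remaining after the rare-gene step. Spike-in
genes contribute to the fraction denominators and are dropped from the
output afterwards; they are excluded from the detected-gene count, since a
well's spike-in signal says nothing about its cellular complexity. MT and
spike-in genes are recognized by identifier prefix (`MT-`, `ERCC-`),
configurable because annotation styles differ.

Because cells removed by the cell filters can push a gene's detection below
3, a second application of `qc_filter` can, on adversarial inputs, remove
additional genes: the one-pass order is deliberate (it mirrors how
plate-data pipelines are run) and re-filtering an already-filtered matrix
is a no-op only when detection counts stay stable.

Normalization is log(TP10K+1) with the natural logarithm:
`x_gc = ln(1 + 10^4 · c_gc / Σ_g c_gc)`. It is scale-free per cell and
strictly monotone in counts within a cell; zero-total cells are an error
that points the caller back to QC.

## Heterogeneity statistics

Expressed genes are those with mean log-normalized expression strictly
above 0.5 over the chosen cell subset. The strict inequality is a
documented boundary decision (the looser "≥" variant appears in informal
descriptions of the same filter); the threshold is configurable. Variance
is the sample variance (n−1); the dispersion index is `D = var/mean` on the
same log-normalized scale so the two rankings are comparable on one gene
set (a raw-count scale is easily obtained by passing a raw matrix's
log-transform; it is not the default). The top-fraction flag marks exactly
`ceil(top_frac · n_genes)` genes, with boundary ties broken
lexicographically by gene id so output is deterministic.

Co-expression uses Spearman correlation with zero values treated as
missing: for each gene pair, only cells where both genes are non-zero enter
the correlation (average ranks for ties, two-sided t-approximation
p-value). In sparse UMI data a zero is mostly a dropout, and including the
joint zero block would manufacture correlation. Pairs with fewer than 3
complete observations are reported as undefined (NaN) rather than raised —
a long marker × partner table should not die on one sparse pair.

## TI phenotype and subgroup classification

The TI phenotype of a trained, restimulated cell is the 6-vector of
differences between its log-normalized marker expression and the mean
log-normalized expression of the restimulated RPMI-control population
(cytokines IL1B, IL6, TNF; chemokines CXCL9, CXCL10, CXCL11). Differences
of log(TP10K+1) values are natural-log fold changes; the alternative
reading (log of the ratio of linear means) is a population-level quantity
and cannot be evaluated per cell, which is why the per-cell difference
definition is used. The control population is all RPMI cells passed by the
caller; restricting it (e.g. per environment) is the caller's choice.

Cells are clustered on the raw 6-D phenotype with complete-linkage
hierarchical clustering and Euclidean distance, cut into exactly three
branches. No standardization is applied: the six coordinates are already on
a common log-FC scale. The distance and linkage follow the hclust
convention this analysis style comes from; both are worth a sensitivity
check on real data, since complete linkage is known to be outlier-driven.

Branches are named by block means: a cluster with both the cytokine-block
and chemokine-block mean log-FC above `activation_threshold = 0` is MCI;
chemokine block only, MC; otherwise NT. When several clusters claim the
same non-NT name, the cluster with the larger summed block means keeps it
and the loser is re-evaluated against the remaining rules (an MCI loser
with an enhanced chemokine block becomes MC; anything else becomes NT).
The cascade matters in practice: the genuine chemokine-only cluster
typically carries a small positive cytokine mean (partially activated MCI
cells fall into it), briefly claims MCI, and must land on MC — demoting it
straight to NT would empty the MC class. The threshold sits at 0 so that
any enhancement over control counts as "enhanced"; it is exposed because a
small positive threshold makes the rule robust to near-zero noise means.

## Rank-AUC signature scoring

Within each cell all genes are ranked by decreasing expression. Ties —
including the large zero block — are broken by a random permutation seeded
from `(tie_seed, cell index)`, so scoring is deterministic given the seed
and no gene is systematically favoured; a deterministic gene-id order would
bias scores toward signatures whose members sort early. Expression values
enter only through ranks, so raw counts and any monotone normalization give
identical scores.

With `k = ceil(top_frac · n_genes)` (default top 3%) and `R(i)` the number
of signature genes at rank ≤ i, the raw area is the step sum
`Σ_{i=1..k} R(i)` and the normalized score divides by the best case of all
`m` detected signature genes occupying ranks 1..m: `Σ_{i=1..k} min(i, m)`.
The convention is pinned by an exhaustive brute-force oracle in the test
suite; a perfectly front-loaded signature scores 1, a signature absent from
the top k scores 0, and promoting a signature gene never lowers the score.

Packaged fixtures: the 9-gene MCI signature (IL1B, IL8, IL6, PTGS2, IL1A,
CCL2, TNF, CXCL3, CXCL1), the 12-gene MC signature (CXCL11, CXCL10, CXCL9,
TNFSF10, HLA-DQA1, FCN1, IGFBP4, HLA-DPB1, HLA-DQB1, FAM26F, RGL1, CD4),
and assignment thresholds 0.544 (MCI) / 0.169 (MC). Thresholds are inputs
estimated from real-data score distributions; re-deriving them is out of
scope. When a cell exceeds both thresholds the signature with the largest
exceedance margin (score − threshold) wins; no published rule covers this
case, so the margin rule is this package's documented choice. On synthetic
data the thresholds are not meaningful: the generator makes the six markers
hyper-abundant, so nearly every cell saturates both scores — threshold
assignment is intended for external (real) datasets.

## Differential expression and TR genes

`wilcoxon_de` tests each gene two-sided with the Wilcoxon rank-sum test
between two disjoint cell groups. Genes non-zero in fewer than
`min_pct = 0.10` of the *tested* group (group 1) are skipped before
testing; the filter is deliberately asymmetric, matching the "at least 10%
expression in the tested group" convention (a symmetric variant is a
one-line change in the caller by intersecting two runs). Bonferroni
correction is applied over the genes actually tested. For
`n1 + n2 ≤ 12` the p-value is exact and tie-aware, computed from the full
null distribution of the rank sum by convolution over doubled average ranks
(doubling makes tied half-ranks integral); larger groups use the
tie-corrected normal approximation with continuity correction. The two
paths agree to |Δp| ≤ 0.02 at n1 = n2 = 6 and the exact path matches full
permutation enumeration bit for bit in the tests. The reported fold change
is `ln((mean(expm1(x̄₁)) + 1) / (mean(expm1(x̄₂)) + 1))` — the
pseudocounted linear-mean ratio customary for this test in single-cell
toolkits; it affects only the reported effect size, never the p-value.

TR (training-response) genes are DE genes between a trained subgroup's
LPS-restimulated cells and the pooled RPMI-control cells, computed per
(subgroup × stimulus) stratum; both directions are kept with the direction
recorded, and the shared summary lists genes significant in ≥2 stimuli per
subgroup. Empty strata are skipped with a logged warning.

## Dirichlet regression

Subgroup compositions are proportions on a simplex, so their components
cannot be tested independently. The model links each concentration
parameter to sample covariates in the common parametrization
`α_ij = exp(x_iᵀ β_j)`; observed zeros are shrunk with the standard
compositional transform `y' = (y(n−1) + 1/J)/n` before fitting. The MLE
maximizes the Dirichlet log-likelihood with its analytic gradient
(digamma terms) under L-BFGS-B, started from moment-matched intercepts;
the group test is a likelihood-ratio test against the intercept-only model
with χ² reference on `(p−1)·J` degrees of freedom. Convergence status and
final gradient norm are reported, and non-convergence is a warning, never a
silent failure. Validation: the log-likelihood agrees with
`scipy.stats.dirichlet.logpdf` to 10 significant digits, the MLE never
falls below the likelihood of the generating parameters, intercept-only
component means are recovered within 5% at n = 2,000 samples, and the null
LRT rejects at ≤10% over 100 seeds at nominal 5%.

## GWAS proximity and over-representation

Gene coordinates follow BED conventions (0-based, half-open); SNP positions
are 1-based. A gene is trait-proximal when the base-pair gap between its
body and the nearest SNP is ≤ the window (default 250,000 bp; a SNP inside
the body gives distance 0). Distance is measured from the whole gene body
because "genes within 250 kbp around SNPs" reads most naturally as interval
proximity; a TSS mode is available. The enrichment test builds the 2×2
table with rows = (trait-proximal, reference-proximal) gene sets and
columns = membership in the TR gene set, and computes the one-sided
(greater) hypergeometric p by summation in log space (log-gamma terms), so
large tables cannot underflow. The alternative table orientation (rows =
TR/non-TR) conditions on the same margins and gives the same one-sided p
when oriented toward enrichment; the packaged orientation is the one that
reads directly as "are TR genes over-represented near trait SNPs relative
to the reference trait". Over-representation on GMT sets is the same
hypergeometric machinery against a user-supplied universe with
Benjamini–Hochberg step-up adjustment (monotone by construction).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
plate-based single-cell scale, with full ground truth:

* Gene baseline weights are lognormal(0, 1); per-cell library sizes are
  gamma (mean 10,000 UMIs, shape 20); donor effects are lognormal per
  (donor, gene) with σ = 0.1 across 3 donors; counts are gamma–Poisson
  (negative binomial, `var = μ + 0.02·μ²`). Per-cell gene weights are
  renormalized before scaling by library size, so boosting markers
  depresses the rest of the transcriptome as in real compositional data.
* The six markers are planted at a baseline weight 3.3 SD above the gene
  mean (~1% of the transcriptome each — cytokine/chemokine transcripts in
  LPS-restimulated macrophages are genuinely this abundant). This keeps
  baseline marker counts strictly positive at study scale, which matters
  because a single zero-count marker produces a log-FC outlier of −4 and
  complete linkage will spend a cluster on it.
* Trained cells draw a latent subgroup from the default mixture
  (0.398, 0.222, 0.380); cytokines are active in MCI, chemokines in MCI and
  MC. Within active cells each marker is independently in a strong state
  (probability `marker_bimodality = 0.7`, log-boost
  `effect + (1−f)·gap`) or weak state (log-boost `effect − f·gap`), with
  `gap = marker_contrast · effect` (defaults 0.5 and 1.5). The mixture
  preserves the subgroup mean log-effect exactly, makes markers
  over-dispersed relative to equally expressed genes, and induces the
  within-block positive correlation seen in the marker analysis, while
  every active cell stays enhanced over control — a hard "off" state
  identical to baseline would scatter active cells across the whole
  phenotype lattice and no 3-cut of a complete-linkage tree could then
  separate the three subgroups (their latent identity would be genuinely
  unobservable for the off cells). Setting both effects to 0 removes all
  planted structure, which is what the null-safety tests exercise.
* The GWAS fixture places genes on one synthetic chromosome spaced more
  than two windows apart (each SNP is proximal to at most one gene),
  designates a random half of genes as the DEG set, plants
  `round(planted_overlap · n_deg)` trait SNPs in-window of distinct DEG
  genes, and places remaining trait SNPs and all reference SNPs near
  uniformly random genes. `planted_overlap = 0` therefore yields a fully
  random (null) placement with approximately uniform Fisher p-values, and
  `planted_overlap = 1` with no surplus trait SNPs yields an infinite odds
  ratio.
* The composition generator draws per-sample proportions from group-wise
  Dirichlet distributions.

What the generator does **not** emulate: ambient RNA, doublets, batch
chemistry, cell-cycle structure, realistic transcriptome-wide gene counts,
or continuous activation gradients between subgroups. Passing recovery
tests on this generator shows the pipeline is correct and well calibrated
under its assumed structure; it does not show that three discrete subgroups
exist in any particular real dataset.

## Null behaviour of the classifier

The three-branch cut always produces three clusters, even on null data, and
the labeling rule then names them from near-zero block means whose signs
are noise. Under a null generator (marker effects 0) the appropriate
expectation is therefore: the positive calls MCI and MC each stay near or
below chance occupancy while NT — the fallback label for clusters with no
enhanced block — absorbs the rest, and TR-gene detection after Bonferroni
returns ~0 genes. The null-safety test asserts exactly this (MCI and MC
mean occupancy within 10 points of 1/3 over 20 seeds); a large NT share
under the null is correct behaviour, not a failure. Users classifying real
data should treat a run where one label's block means hover at ±0.01 as
unclassifiable rather than as evidence of training.

## Problem sizes and runtimes

The validation suite runs the full study scale where the claim demands it
(composition recovery: five datasets of 5,000 trained + 2,000 control
cells, 2,000 genes) and reduced but structurally identical scales
elsewhere, as the package's own choice of test economy: marker
heterogeneity over 50 seeds at 1,200 + 600 cells; null safety over 20 seeds
at 900 + 450 cells; Dirichlet calibration over 100 seeds at 10 samples per
group with recovery at 2,000 samples. The acceptance script
(`scripts/acceptance.py`) re-runs the five full-scale datasets from scratch
in about 20 seconds on one CPU.

## Known limitations

* Complete linkage at k=3 is sensitive to extreme cells; a handful of
  outliers can consume a branch. On real data, inspect the dendrogram and
  consider a small positive `activation_threshold`.
* The exact Wilcoxon path is O(n1 · Σrank) per gene and is enabled only for
  n1 + n2 ≤ 12; beyond that the tie-corrected normal approximation is used.
* Dirichlet regression uses one shared design across components (no
  component-specific formulas) and the alternative mean/precision
  parametrization is not implemented.
* `assign_by_threshold` presumes scores computed the same way as when the
  thresholds were estimated; packaged thresholds are only meaningful for
  real datasets scored with the packaged signatures.
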