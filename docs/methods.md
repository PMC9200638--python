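# Methods

`pansvherit` implements the statistical machinery for asking how much trait
heritability is carried by structural variants (SVs) that a single linear
reference genome fails to catalogue, and what that buys for mapping and
breeding: partitioned-kinship REML, leave-one-chromosome-out (LOCO)
mixed-model association, multilocus LASSO mapping with permutation
significance, signed co-expression module detection, and GBLUP genomic
selection — plus a synthetic-population generator so every stage runs and is
tested without external data.

## The variance-component model

For a quantitative trait on n inbred accessions,

    y = X b + sum_k g_k + e,    g_k ~ N(0, sigma2_k K_k),   e ~ N(0, sigma2_e I)

with one genomic relationship matrix (GRM) K_k per variant category (SNP,
indel, SV; or cis/trans crosses of those).  The GRM uses the MAF-weighted
parameterization

    K = (1/c) sum_j s_j (x_j - 2 f_j)(x_j - 2 f_j)',   s_j = [2 f_j (1 - f_j)]^alpha,

which makes the expected per-variant heritability proportional to
[f_j(1-f_j)]^(1+alpha) under standardized effects.  `alpha = -0.5` is the
default (per-variant heritability tapering with decreasing MAF); `alpha = -1`
recovers the fully standardized GRM.  `c` normalizes the mean diagonal to 1
so variance components are comparable across partitions; it is additive over
disjoint partitions, which the tests exploit (scale-weighted partition GRMs
sum to the whole-set GRM to 1e-10).

REML is maximized by average-information updates with step-halving and an
EM fallback whenever an AI step would lower the restricted likelihood or
leave the feasible cone.  With `constrain=True` a component pinned at zero
is removed and the model refit, so no negative heritability is reported
(its share is exactly 0).  Standard errors come from the inverse AI matrix;
share (h2) standard errors by the delta method.  BLUPs are
sigma2_k K_k V^{-1}(y - X b).  Fixed effects default to an intercept plus
the first four genotype PCs computed from SNPs+indels (deterministic sign
convention: the largest-magnitude loading of each PC is positive).  A
fast single-GRM path (eigen-rotation profile likelihood, bounded scalar
optimization on h2) serves the LOCO scan and GBLUP; it is itself checked
against the general AI-REML fit and an independent grid-search oracle.

Heritability categories place each trait's (SNP, indel, SV) share vector on
the simplex and assign the nearest of seven anchors (three vertices, three
edge midpoints, the centroid — labelled SNP, INDEL, SV, SNP+INDEL, SNP+SV,
INDEL+SV, ALL).  The anchor coordinates are configurable; the defaults are
this package's choice of a symmetric layout, since no canonical coordinates
are fixed by the category names alone.

## Association and QTL calling

The LOCO mixed model estimates, per chromosome c, the variance components of
y under a GRM built from LD-pruned variants of all other chromosomes
(pruning dialect `-indep-pairwise 50 5 0.2`: 50-variant windows advancing by
5, pairwise r2 cap; the kilobase dialect `--window-kb` is also provided,
pruning greedily left-to-right and dropping the lower-MAF member of a
violating pair, tie broken to the later position; count-window pruning
iterates to a fixpoint over the condensed kept set so it is idempotent).
Each variant on c is then Wald-tested by GLS with the chromosome's fixed
variance ratio (the GCTA-MLMA / GRAMMAR approximation — one variance fit
per chromosome, reused across variants).  Single-chromosome inputs fall
back to a whole-genome GRM with a warning.  Significance uses the
Bonferroni threshold -log10(0.05/m).  Significant variants are clustered
left-to-right into QTLs when adjacent variants have r2 > 0.20 and distance
< 1 Mb; clusters need more than three members (>= 4).  An eQTL is cis when
its leading variant (minimum p, ties to the smaller position) lies within
50 kb of the gene start or end on the same chromosome.

## Multilocus LASSO with first-entry permutation p-values

The evidence statistic per variant is the LARS penalty at which it first
enters the active set (for the first entrant, lambda_max = max|x'y|/n on
standardized predictors).  Significance is by permutation: permuting the
response and sorting each permutation's entry penalties gives a null
distribution per *rank*; the variant of observed rank r is compared with
the rank-r order statistic, p = (1 + #{null >= observed})/(n_perm + 1).
The sorted p multiset is then reassigned in entry-penalty order
(an isotonization that leaves all discovery counts — hence calibration —
untouched while making p monotone in the statistic).  Selection uses the
1/m threshold, which by construction yields about one expected null
discovery per scan; the permutation FDR at the threshold is the mean
permuted discovery count over the observed count (undefined at zero
observed discoveries).  Exact duplicate predictors inherit their twin's
entry penalty; simultaneous entries tie-break to the lower column index.
This permutation scheme replaces an analytic first-entry null: it
reproduces the ranking and threshold behaviour, is seedable, and is exact
at the scan sizes used here; exact numeric parity with any closed-form
null is not claimed.

Workflows: a *cis-SV scan* runs the LASSO on the SVs within a gene's
+/-50 kb window against its (preprocessed or BLUP-summarized) expression
and flags allelic heterogeneity when >= 2 SVs are significant; the
*module-guided trait scan* first keeps module genes with significant
cis-SV eQTLs, pools their cis-SVs, scans the pool against the trait, and
reports each significant SV with its host gene and a two-sided Wilcoxon
contrast of the trait between homozygous genotype groups.  The recommended
LASSO response is the summed component BLUPs of a composite REML fit;
the raw preprocessed trait is accepted wherever a BLUP is not supplied.

## Co-expression modules

Signed adjacency a_ij = ((1 + cor_ij)/2)^beta (default beta = 9; a
scale-free-fit chooser over beta = 1..20 is provided), topological overlap
TOM_ij = (sum_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 - a_ij), average-linkage
clustering of 1 - TOM with a *static* height cut (default: the 0.99
quantile of merge heights, configurable — the dynamic tree-cut algorithm is
deliberately not reimplemented), minimum module size 10, grey for the
unassigned, and iterative merging of modules whose eigengenes (first PC of
the module expression, unit norm, sign aligned to the mean profile) are
closer than dissimilarity 0.15.  Static cuts are cruder than dynamic ones:
with pure-noise backgrounds, hub modules attract noise genes, so fixtures
for fine-grained behaviour use structured backgrounds and a lower cut
quantile.  Labels are size-ranked (M1 largest) and invariant to gene order
up to relabelling.

## Genomic selection and MAS

GBLUP is solved in the kinship parameterization: per training fold the
variance ratio is estimated by the eigen-rotation REML, and held-out
breeding values come through the kinship cross-block,
g_test = K[te,tr](K[tr,tr] + (sigma2_e/sigma2_g) I)^{-1}(y_tr - mu).
Accuracy is the squared Pearson correlation of pooled predictions with
observed phenotypes per repetition, averaged over five repetitions of
five-fold cross-validation (fold assignments are seeded and shared across
marker sets so comparisons are paired).  `compare_marker_sets` builds one
GRM per marker set and compares accuracies across traits with the paired
two-sided Wilcoxon signed-rank test.  MAS groups accessions by their count
of favorable homozygous SV genotypes and contrasts trait distributions
between groups (rank-sum), flagging when the all-favorable group's median
beats every single-marker group.

## Phenotype preprocessing

Expression (TPM): genes expressed (TPM > 0.5) in >= 100 accessions are
kept; each gene is rank-transformed to normal scores with offsets
(r - 0.5)/n (ties share average rank); the top four expression PCs are
regressed out as nuisance factors — a deterministic substitute for latent
factor residualization, appropriate because the factors serve only as
covariates — and residuals are rescaled to unit variance.  Metabolites:
traits missing in >= 100 accessions are dropped, replicate pairs averaged,
intensities transformed by the ternary logarithm (log base 3; nonpositive
values are an error naming the trait) and quantile-normalized; residual
missing entries are set to the normal-score mean (0) so retained traits
are complete.  Genotypes: missing dosages are mean-imputed per variant;
association stages default to MAF >= 0.01, heritability stages use all
variants passing missingness.

## The synthetic population

The generator emulates the statistical structure the analyses assume, not
tomato biology.  Defaults are the study conditions: 332 accessions in
three subpopulations (fractions 217/98/17), fully homozygous (dosages in
{0,2}), six chromosomes of 2 Mb carrying 700 SNPs, 70 indels and 35 SVs
each (the ~13:1.3:1 class ratio at desk scale), SV tag-R2 targeted at a
median of 0.70, and a degraded "linear-style" callset retaining 20% of SVs.

Mechanism: founder-mosaic, not coalescent.  Per subpopulation, a small
founder panel (8 haplotypes) is drawn around shared ancestral frequencies
with Balding–Nichols drift (Fst = 0.15, enough for the first genotype PCs
to separate subpopulations at silhouette > 0.5); each accession is a
homozygous recombinant mosaic of its founders (Poisson(3) crossovers per
chromosome).  Each SV column is then re-derived from its nearest
polymorphic small variant within 50 kb and degraded by calibrated allele
flips until the squared correlation with its tag matches a per-SV target
drawn around the configured median — direct control of incomplete LD, the
quantity under study.  A target of 1.0 duplicates the tag column exactly.
A configurable number of genes is forced to carry two low-MAF cis-SVs
(carrier counts matching MAFs ~0.017 and ~0.032) for the
allelic-heterogeneity scenarios.

Traits use *in-sample exact* variance scaling: per-class genetic scores are
sequentially orthogonalized and rescaled so realized variance fractions
equal their targets to machine precision, and the residual is drawn
orthogonal to all of them.  This makes parameter-recovery tests sharp at
n = 332 (the estimator's Monte-Carlo spread is not confounded by sampling
noise in the simulated h2 itself); the cost is a small deviation from a
purely additive draw, negligible when cross-class causal correlations are
weak.  Effect sizes follow the same [f(1-f)]^(1+alpha) weighting as the
estimation side, alpha = -0.5.  Allelic-het traits place their SV variance
in one gene's window on a polygenic SNP background (default 0.20) —
without a background, genome-wide kinships see a two-rare-variant trait as
pure noise, which is not the regime of interest.  Module traits flow from
a latent factor through several genes' cis-SVs into the trait, with a
companion expression simulator planting the corresponding co-expression
blocks.

One identifiability caveat: because every variant class segregates on the
same founder mosaic, the per-class kinships share most of their structure
(off-diagonal correlations ~0.9 between the SNP and indel GRMs at the
default founder-panel size).  Composite *total* heritability is therefore
well identified, while individual SNP/indel shares are anti-correlated
with wide Monte-Carlo spread — recovery experiments report means over
replicate populations and traits with Monte-Carlo standard errors, and
bias bounds scale with that spread.  Real panels are richer in haplotype
diversity; this caveat is a property of the desk-scale founder design, not
of the estimator.

What the generator does not emulate: real linkage maps and recombination
hotspots, selection and demography, multiallelic/complex SVs, genotyping
error, and expression count noise.  Passing tests therefore demonstrate
correctness and calibration of the machinery under the stated statistical
structure, not performance on any particular real dataset.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale, the package's own
choice for routine verification: populations of ~1,000–7,500 variants,
10–30 trait replicates per experiment, 120–300 permutations per LASSO
scan, 300–500 null traits for calibration.  Monte-Carlo tolerances scale
accordingly (bias bounds use 2 Monte-Carlo SEs of the replicate mean).
Convergence: REML tolerance 1e-6 on the restricted likelihood, max 200
iterations, variance floor 1e-8 * var(y); GRMs are symmetrized and
eigenvalues clipped at 0; degenerate inputs (monomorphic variants,
constant genes, empty windows, all-missing columns) are dropped with
warnings or produce explicit empty/flagged results rather than errors,
except where the input is unusable (nonpositive intensities before the
ternary log, multiallelic VCF records, missing SVLEN).

## Known limitations

* The static tree cut plus eigengene merging is a deliberate
  simplification of dynamic tree cutting; module boundaries in noisy data
  differ from a dynamic-cut run.
* The GRAMMAR-style fixed-ratio Wald test slightly deflates statistics for
  variants in strong LD with the (excluded-chromosome) polygenic
  background; the null calibration test bounds the practical effect.
* Permutation p-values are granular at 1/(n_perm + 1); scans needing
  p << 1/m must raise n_perm.
* The LASSO significance threshold 1/m is a calibration convention, not an
  FWER/FDR guarantee; the permutation FDR estimate quantifies the realized
  rate.
* GBLUP assumes a single homogeneous variance ratio per trait; no
  multi-environment or non-additive terms.
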