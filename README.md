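# pansvherit

Statistical machinery for the question: **how much trait heritability is
carried by structural variants (SVs) that a linear reference genome fails to
catalogue — and what does recovering them buy for mapping and breeding?**

When causal SVs are absent from a callset, tag markers in incomplete
linkage disequilibrium (R² < 1) absorb only part of their variance, so
estimated heritability drops; allelic heterogeneity (several causal
variants at one locus) and locus heterogeneity (several loci behind one
trait) further erode single-variant association power.  `pansvherit`
implements the full analysis chain used to study this on a diversity panel
of inbred accessions, together with a synthetic-population generator that
reproduces the relevant statistical structure, so every stage runs, and is
tested, offline.

The pipeline, for accessions i = 1..n with dosage matrix X:

* **Partitioned heritability.**  y = Xb + Σₖ gₖ + e with gₖ ~ N(0, σ²ₖ Kₖ),
  one MAF-weighted kinship per variant class,
  K = (1/c) Σⱼ sⱼ (xⱼ − 2fⱼ)(xⱼ − 2fⱼ)ᵀ, sⱼ = [2fⱼ(1−fⱼ)]^α, α = −0.5;
  average-information REML with an EM fallback and non-negativity
  constraints; h²ₖ = σ²ₖ / Σσ².
* **Association.**  Leave-one-chromosome-out mixed-model scan (per-chrom
  variance ratio, GLS Wald tests), Bonferroni threshold
  −log₁₀(0.05/m), QTL clustering (adjacent r² > 0.2 within 1 Mb, ≥ 4
  members), cis/trans calls at a 50-kb gene window.
* **Multilocus LASSO.**  Per-variant first-entry penalty λ_entry along the
  LARS path, permutation p-values per rank, significance at 1/m,
  permutation FDR; cis-SV scans flag allelic heterogeneity (≥ 2
  significant SVs per gene) and a co-expression-module-guided two-stage
  scan resolves locus heterogeneity.
* **Co-expression modules.**  Signed adjacency ((1+cor)/2)^β (β = 9),
  topological overlap, average-linkage clustering with a static cut,
  minimum module size 10, eigengene merging at dissimilarity 0.15.
* **Genomic selection.**  GBLUP in the kinship parameterization with
  5-fold × 5-repetition cross-validation; accuracy r² between phenotype
  and genome-estimated breeding values; marker-set comparisons and
  SV-based marker-assisted selection.
* **Synthetic panel.**  332 homozygous accessions in 3 subpopulations,
  founder-mosaic haplotypes, SV tag-R² with median ~0.70, a degraded
  callset retaining 20% of SVs, and traits with in-sample-exact per-class
  heritability (defaults 0.10 / 0.04 / 0.27 for SNP / indel / SV).

## Worked example

```bash
python analysis/01_simulate_population.py 1
python analysis/02_heritability_partition.py 1
```

prints, for seed 1:

```
accessions: 332, variants: 4568 (210 SVs)
SV max tag-R2: median 0.69, complete LD in 2.9%
linear-style callset keeps 20% of SVs
...
                  mean_h2  median_h2  n_traits
composite_graph     0.375      0.347        12
snp_indel_linear    0.295      0.307        12
percent increase of composite over degraded SNP+indel: 27% (Wilcoxon p = 0.0941)
direction (composite > degraded) in 100% of traits
```

Read: on traits whose largest variance share sits in SVs, the composite
SNP+indel+SV model on the full callset recovers more heritability than a
SNP+indel model on the SV-depleted callset — the missing-heritability gap
attributable to incomplete LD.  The remaining drivers
(`03_allelic_heterogeneity.py`, `04_module_locus_heterogeneity.py`,
`05_genomic_selection.py`) run the allelic-heterogeneity power comparison
(LASSO vs single-variant scan), the module-guided locus-heterogeneity
search, and the SV-vs-SNP genomic-selection comparison; each writes its
tables under `results/`.

The exact numbers vary with the seed; every table is accompanied by a
manifest (seed, parameters, version) sufficient to replay the run.

## Layout

```
src/pansvherit/     library: genio, synthpop, kinship, varcomp, assoc,
                    lassoml, coexpr, gsel, workbench
analysis/           numbered narrative drivers writing results/
scripts/acceptance.py
docs/methods.md     model assumptions, parameter choices, limitations
tests/              pytest suite incl. acceptance criteria
```
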