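# stratenrich

Stratified enrichment of GWAS associations in annotated variant sets.

Complex-trait GWAS signal is not spread uniformly across the genome: variants
that regulate gene expression (eQTLs), sit in promoters or enhancers, or lie
close to transcription start sites associate with traits at different rates.
`stratenrich` quantifies that excess for any annotated variant set — per-tissue
eQTL panels, chromatin-state categories, TSS-proximal/distal strata — relative
to control variants matched on minor allele frequency and distance to TSS,
using nothing but GWAS summary statistics, the annotation memberships, and
pairwise LD. It is written for statistical geneticists who have summary
statistics and annotation files and want a tested, reproducible enrichment
pipeline plus the individual building blocks as a Python library.

## The method

For each variant, the two-sided association p-value is converted to a 1-df
chi-squared statistic, z² = (Φ⁻¹(p/2))². The pipeline then:

1. draws ten random LD-pruned replicas (maximal near-independent sets with
   r² < 0.2 within 1 Mb, fresh random ordering per replica);
2. applies genomic control, λ = median over replicas of the per-replica median
   intergenic χ², divided by the null median m₀ ≈ 0.455; all χ² are divided by
   λ and p-values regenerated;
3. draws stratified Q-Q curves and conditional fold-enrichment curves,
   FE(t) = [#{S : −log₁₀p ≥ t}/|S|] ÷ [#{controls : −log₁₀p ≥ t}/|controls|];
4. fits, on every replica, the chi-squared general linear model
   E[χ²] = β₀ + β_eQTL·x_eQTL + β_ctrl·x_ctrl + Σ_c β_c·x_c + β_LD·totLD
   (chromatin categories c; total LD score totLD = 1 + Σ r²), optionally with
   eQTL × category and eQTL × totLD interaction terms, and meta-analyzes the
   ten fits (fixed-effect inverse variance; β̄ = mean replicate coefficient);
5. compares χ² between annotated and control variants by Mann-Whitney rank
   test and estimates the non-null proportion π1 = 1 − π0 by the Storey
   π0(λ)-grid estimator, both on the full unpruned variant set;
6. intersects annotations with r² ≥ 0.8 LD windows around
   genome-wide-significant loci and reports the ratio of proportions
   (K/N) ÷ (k/n) between the genome-wide representation of the annotation
   (K of N independent loci) and the observed locus overlap (k of n loci),
   with a two-sided Fisher exact test.

A first-class synthetic-data module generates variant maps with block LD
(exact pairwise r² emitted), tissue-tagged eQTL sets with 10% cross-tissue
sharing, matched-control pools, and GWAS z-scores drawn jointly within LD
blocks with annotation-dependent variance inflation — so every stage of the
pipeline is exercised and validated end to end without any external download.
See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

`examples/02_glm_meta_enrichment.py` simulates 50,000 variants in which every
eQTL carries a 0.20 inflation of its expected association χ² under a genomic
inflation of λ = 1.1, then runs pruning, genomic control and the meta-analyzed
GLM:

```
genomic inflation: true lambda = 1.1, estimated = 1.145

term         beta_bar   95% CI            meta p
eqtl:all        0.187   [ 0.162,  0.212]  7.49e-48
control:all    -0.008   [-0.032,  0.015]  4.90e-01
total_ld        0.001   [-0.003,  0.006]  4.93e-01
```

The eQTL coefficient recovers the designed 0.20 (β̄ = 0.187): eQTLs carry an
excess of ~0.19 association χ² per variant after adjusting for matched
controls and LD-tagging power, while the matched controls and the LD covariate
sit at zero. (The λ estimate slightly exceeds 1.1 because genomic control
absorbs part of the eQTL signal through the intergenic median — a property of
the correction, discussed in the methods note.) `examples/04_locus_overlap.py`
prints the locus-overlap contrast for a published-scale 2×2 table:

```
baseline designated cis-eQTLs        : K/N = 0.0280, k/n = 0.1172, ratio = 0.24, Fisher p = 3.4e-06
baseline independent promoter loci   : K/N = 0.0320, k/n = 0.1172, ratio = 0.27, Fisher p = 1.6e-05
```

i.e. significant loci contain an eQTL in their LD window about four times more
often than the annotation's genome-wide footprint predicts. The other examples
cover fold-enrichment/Q-Q curves, π1 and rank tests, and the one-call pipeline
(`run_all`), which writes fold curves, GLM tables, genomic-control factors, a
cross-trait summary table and a manifest under an output directory. A thin CLI
(`stratenrich simulate|prune|gc|overlap|run`) wraps the same functions.

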