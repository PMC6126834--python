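# Methods

`stratenrich` quantifies the excess of trait associations among annotated
variant sets — tissue eQTL panels, chromatin-state categories,
TSS-proximal/distal strata — relative to matched control variants, from GWAS
summary statistics alone. This note describes the statistical procedure, the
synthetic data it is validated on, the numerical choices, and the known
limitations.

## The procedure

**From p-values to χ².** Each two-sided association p-value is converted to
the 1-df chi-squared statistic z² = (Φ⁻¹(p/2))², computed as the χ²₁ inverse
survival function for numerical stability. The conversion is strictly
decreasing and round-trips with its inverse to 1e-10 relative tolerance over
p ∈ [1e-12, 1].

**LD-pruning replicas.** Annotated variants are not independent; instead of
committing to one arbitrary LD-independent representative set, ten maximal
near-independent subsets (r² < 0.2 within 1 Mb, defaults exposed) are drawn
by greedy selection under fresh random permutations. Every retained set is a
maximal independent set of the conflict graph under its own ordering, so no
retained pair violates the threshold (verified by exhaustive scan in the
tests). Replicas may overlap; a `disjoint` flag provides the alternative
reading in which later replicas exclude earlier picks. Missing pairs in the
sparse LD list are treated as r² = 0. All replica seeds are recorded for
exact replay.

**Genomic control.** The inflation factor λ is the median over replicas of
the per-replica median intergenic χ², divided by the null χ²₁ median
m₀ ≈ 0.454936 (computed from the quantile function, never hard-coded). All
χ² are divided by λ and p-values regenerated before any enrichment
modelling, so curves, rank tests and π1 all see corrected statistics. The
correction preserves p-value ranks and is idempotent: re-estimating λ after
correction returns exactly 1. Genic/intergenic status is an input flag; with
polygenic signal concentrated in annotations that reach intergenic space the
estimator deliberately absorbs some true signal, which is a known property
of genomic control, not a defect of the estimator.

**Enrichment curves.** Stratified Q-Q points use rank-midpoint plotting
positions, expected_i = −log10((i − 0.5)/n). Fold enrichment at threshold t
is the ratio of complementary empirical CDFs of −log10(p) between the
annotated set and its baseline (the matched controls by default, any set on
request); thresholds ascend in 0.1 bins and are truncated where the baseline
denominator falls below a floor (default 10) so the right tail is never a
ratio of near-empty counts.

**Rank tests and π1.** Mann-Whitney comparisons of χ² between an annotated
set and its matched controls run on the full (unpruned) variant set; the
exact null distribution is enumerated when min(n) ≤ 8 without ties,
otherwise the tie- and continuity-corrected normal approximation is used.
π1 = 1 − π0 is the Storey estimate: π0(λ) = #{p > λ}/(n(1 − λ)) on a
λ-grid 0.05…0.95 (step 0.05), smoothed by a cubic least-squares polynomial
and read off at the largest λ, then clamped to [0, 1]. The cubic polynomial
(4 effective df) stands in for the customary df≈3 smoothing spline: it is
deterministic, linear in the data, and agrees with the spline to well within
the estimator's Monte-Carlo noise at these grid sizes.

**Chi-squared general linear model.** On each pruning replica, the corrected
χ² is regressed by OLS (Gaussian family, identity link; statsmodels) on
annotation indicators (eQTL per tissue, matched controls, chromatin-state
categories, proximal/distal), the continuous total LD score
(1 + Σ r² over partners within 1 Mb, self-count included — the constant is
absorbed by the intercept), and optional interactions (eQTL × chromatin
category, eQTL × total LD). The χ² response is heteroskedastic; classical
SEs are the default to mirror standard practice, with an HC1 robust option.
Scope is either the full template (unannotated variants as reference) or
eQTLs-and-controls only (controls as reference). Degenerate (constant)
columns and rank deficiency are hard errors naming the offending terms.

**Meta-analysis across replicas.** Per-term replicate coefficients are
combined by fixed-effect inverse variance; the headline effect size β̄ is the
plain mean of replicate coefficients, reported alongside the pooled estimate
with its 95% CI and p. The combination deliberately ignores the correlation
induced by replica overlap. This makes meta p-values anti-conservative —
measured on null simulations in this package, a nominal α = 0.05 meta test
rejects at roughly 0.3, while each single-replica test is calibrated
(≈ 0.04). The choice is retained because it is the procedure being modelled;
treat meta p-values as a ranking device, not calibrated error rates, and see
the per-replica tables emitted alongside. Correlation-aware standard errors
are out of scope by design.

**Matched controls.** Controls are drawn without replacement from the
(MAF bin, TSS-distance bin) stratum of each target variant — 2%-wide MAF
bins, deciles of log10(1 + distance) — after excluding any candidate with
expression-association p < 1e-4 (absent means p = 1). The per-stratum draw
is round(ratio × stratum size) with ratio defaulting to 1.2, the aggregate
control:eQTL proportion of the data the design emulates. Empty strata leave
their targets reported as unmatched rather than failing. Diagnostics compare
MAF, TSS distance and total LD between targets and controls by rank test;
an excess of total LD among targets is the expected signature that the two
matching proxies do not capture LD-tagging power.

**Locus overlap.** For each genome-wide-significant lead variant, the LD
window is the lead plus all variants with r² ≥ 0.8 to it (inclusive); a
locus overlaps an annotation when at least one annotated variant is in the
member set (an interval mode using the spanning base-pair range is
available). The overlap fraction k/n is contrasted with the genome-wide
fraction K/N of independent loci represented by the annotation; K and N are
inputs, since they are estimated outside summary statistics. The printed
enrichment ratio is the ratio of proportions (K/N)÷(k/n) — with the
reciprocal and the odds-ratio variant also emitted — plus a two-sided Fisher
exact p on [[k, n−k], [K, N−K]].

## The synthetic generator

The generator (`synthetic_data`) produces the complete input surface in the
exact formats the readers accept, so the pipeline can be validated end to
end without any download.

* **LD**: blocks of 20 variants spanning 60 kb (desk default), zero LD
  across blocks. Within a block, variant i has loading ρ_i ~ Beta(2, 2) on a
  shared haplotype factor, giving pairwise r²(i,j) = ρ_i·ρ_j. This yields a
  broad r² spectrum straddling the 0.2 pruning threshold (so pruning is
  consequential, not cosmetic) and an exactly known, PSD correlation
  structure for joint z draws.
* **Annotations**: per-tissue eQTL fractions of 2% at desk scale — large
  enough that annotated strata contain thousands of variants at 100k — with
  a common shared core sized to give exactly 10% pairwise overlap between
  tissues, the cross-tissue sharing level typical of single-tissue eQTL
  panels. Four chromatin-state categories at fractions 3/3/4/5%, a genic
  flag at 50%, MAF uniform on [0.01, 0.5], TSS distances log-uniform on
  [1 kb, 500 kb] so the 25 kb proximal/distal split is non-degenerate.
* **Association statistics**: within a block,
  z_i = σ_i(√ρ_i·u_b + √(1−ρ_i)·e_i), so corr(z_i, z_j) = √(ρ_iρ_j) matches
  the emitted r² and E[z²_i] = σ²_i. Enrichment enters as
  σ²_i = λ(1 + Σ_k β_k x_ik + β_LD(totLD_i − 1)) on the non-null fraction of
  each class — effects on the E[χ²] scale, making the linear-in-χ² model
  correctly specified, so a fitted coefficient estimates its configured β_k
  directly. Desk defaults: β_eqtl = 0.20 (the magnitude of the strongest
  per-tissue effects the design emulates), λ = 1.1, β_LD = 0. β_LD defaults
  to zero because a genuine LD-tagging variance term inflates the intergenic
  median and is therefore partially absorbed by genomic control, deflating
  every coefficient — real GC behaves the same way; unit tests exercise
  β_LD ≠ 0 against uncorrected statistics.
* **Seeding**: all randomness flows from one seed through
  `numpy.random.SeedSequence([seed, stream…])`: stream 0 the variant map,
  (1, i) the GWAS for trait i, 2 the expression-association p-values. The
  same seed reproduces fixture files byte for byte.

What the generator does **not** emulate: realistic human LD maps, MAF–LD
coupling, MAF-dependent power, population stratification beyond a scalar λ,
linked selection, or eQTL effect-size distributions. Passing tests therefore
demonstrate that the estimators recover what they are defined to estimate
under the assumed data-generating process — not that real-data effect sizes
would be unbiased under model misspecification.

## Numerical choices and degenerate inputs

* p = 0 in GWAS exports is clamped to 1e-300 (configurable) with a counted
  warning; p outside [0, 1] or unparseable rows are dropped and counted.
* Variant positions are 1-based; BED is 0-based half-open; the conversion
  lives in a single predicate (`bed_contains`). Zero-length BED intervals
  contain nothing; unknown chromosomes warn and skip.
* Fold-curve ratios are only reported where the baseline denominator meets
  the floor; at threshold 0 with complete sets the ratio is exactly 1.
* An isolated variant has total LD score exactly 1; a lead without LD
  partners has a zero-length window at its own position; zero locus overlap
  leaves the enrichment ratio NaN (flagged) rather than failing.
* Ties in the Mann-Whitney exact branch force the corrected asymptotic path;
  identical distributions short-circuit the diagnostics rank test to p = 1.
* Greedy pruning tie-breaks are the permutation order itself; with a fixed
  seed the replicas are bit-reproducible across platforms via
  `numpy.random.default_rng`.

## Problem sizes used in validation

The acceptance suite runs the full pipeline at 100k variants (effect
recovery), 200 null simulations at 20k variants (calibration of curves and
GLM), 50k-variant interaction scans, and 50k-sample π1 mixtures — sizes at
which every Monte-Carlo tolerance asserted is at least ~2 estimator SDs,
while the whole suite stays in the minutes range on a single core.

## Known limitations

* Meta p-values across overlapping pruning replicas are anti-conservative
  (see above); the per-replica coefficient tables are the calibrated unit.
* π1 on mildly inflated χ² (variance inflation rather than sparse strong
  effects) estimates a genuinely small non-null proportion; it recovers the
  designed π1 only when alternatives are well separated from the null.
* Genomic control absorbs polygenic signal carried by the intergenic median;
  coefficients after correction are conditionally deflated by design.
* The locus-overlap baseline K/N is an external input; no attempt is made to
  estimate the number of independent genomic loci.
* eQTL mapping, chromatin-state learning, liftover, allele harmonization and
  VCF parsing are out of scope.
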