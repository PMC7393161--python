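# Methods

This note documents the models and procedures implemented in `eyemorph`,
the choices made where the design was genuinely open, and what the
synthetic-data generators do and do not emulate.

## Geometric morphometrics (`eyemorph.morpho`)

**Alignment.** Landmark configurations (43 two-dimensional points per head
by default) are superimposed by generalized Procrustes analysis: each
configuration is centered, scaled to unit centroid size, and iteratively
rotated to the running consensus until the consensus moves by less than
1e-10. Reflections are forbidden (heads are imaged in a consistent
orientation; allowing reflection could silently flip a specimen). Aligned
coordinates are therefore pure shape variables; centroid size is retained
as the size variable.

**Projection-artifact removal.** Heads are 3D objects photographed in 2D,
so small pitch (up/down) and yaw (left/right) rotations of the mount
masquerade as shape variation. The correction is a two-step pooled
regression: (1) a PCA of the group-mean-centered (pooled within-group)
coordinates is computed, every coordinate is regressed — pooled within
groups — on the PC1 score, and the residuals are kept (group means are
preserved exactly because the score is centered within each group);
(2) the procedure is repeated on the corrected data, removing the *new*
PC2. Which axis is removed at each step is configurable (`axes=(1, 2)` by
default) because the axis on which an artifact loads is an empirical
property of each data set. The PCA centering (pooled vs. global) is also
configurable; pooled centering is the default since the artifact is a
within-group phenomenon. The procedure can only remove an artifact that
is spectrally identifiable: if two variance sources have nearly equal
within-group amplitude, the sample PC mixes them and the residual carries
part of both.

**Dimension reduction with back-rotation.** To avoid more variables than
specimens in the group tests, a PCA retains the smallest number of axes
whose cumulative variance reaches the target (0.90 by default; ties keep
the smaller k), and the reduced scores are rotated back into landmark
space (scores·basisᵀ + mean) so that downstream distances remain
interpretable as landmark displacements.

**Group discrimination.** CVA takes the canonical axes from the
eigen-decomposition of (pooled within-group covariance)⁻¹ × between-group
covariance. Rank-deficient input (back-rotated coordinates) is first
projected losslessly onto its non-null principal subspace; if the pooled
within-group covariance is singular there, the analysis refuses and asks
for stronger dimension reduction. Pairwise group separation is reported
as the Mahalanobis distance on the pooled within-group covariance and as
the Procrustes distance between mean shapes. Inference is by permutation
of group labels on the two-sample Hotelling T² statistic with
p = (b+1)/(n_perm+1) (the observed statistic counts in both tallies, so
p is never 0; the minimum attainable p is 1/(n_perm+1)). DFA is the
two-group special case with a single discriminant axis oriented from the
first group's mean toward the second's (so relabelling flips score
signs), 1,000 permutations by default, and a leave-one-out cross-
validated misclassification rate reported separately from the permutation
test.

**Allometry.** The allometric component of shape is the per-coordinate
linear regression on centroid size; its residuals are the non-allometric
component used for chromosome-effect testing.

## Size correction (`eyemorph.sizecorr`)

Tibia size is summarized as GMsqT = (t1²·t2²·t3²)^(1/3) and overall body
size as GMsqTW = (t1²·t2²·t3²·W)^(1/4), treating the three squared tibia
lengths and the wing area symmetrically; the alternative reading
(geometric mean of GMsqT and W) is available via `mode="gm_of_gm"`.
Size-corrected eye area is the residual of eye area on GMsqTW (optionally
plus the grand mean for display on the µm² scale). *Relative eye size* is
the residual of the multiple regression of eye area on tibia size and
wing area, plus the grand mean of eye area. This is deliberately
conservative: any genetic effect acting through body size is absorbed by
the correction, so a chromosome that affects both body and eye size has
its direct eye effect attenuated by the fraction of its variance the
body-size predictors explain (about 8% for the 5th-chromosome default
below).

Allometric coefficients are slopes of log eye area on log GMsqTW per
group; slope differences are tested with a size×group interaction in a
linear model. Missing wing areas are imputed from the multiple regression
of wing area on the three tibia lengths. Group testing uses
Kruskal–Wallis followed by Dunn's rank-based z-tests with tie correction,
or pairwise Wilcoxon rank-sum (exact where sample size permits), with
Holm step-down adjustment within each family of pairwise comparisons.
All tests are two-sided.

## Backcross chromosome models (`eyemorph.backcross`)

In a backcross each chromosome is a two-level factor (homozygous
recurrent parent vs. heterozygous). Individuals discordant within a
linked marker pair are excluded as recombinants, as are donor-parent
homozygotes (impossible under the design); the exclusion log records the
reason per individual. Chromosome effects on relative eye size come from
simple linear models; the effect is reported as the percent change of the
het-class mean relative to the hom-class mean (identical to the model
coefficient scaled by the hom mean for a two-level factor) with the
model's R² and p. Note the percent denominator is the hom-class mean of
*relative* eye size, which includes half of every other chromosome's
effect; with the default effect sizes this compresses the printed
percentages by roughly 5–8% relative to the planted generative values,
while the model coefficient itself is unbiased for chromosomes without a
body-size channel. Epistasis is probed by adding all interaction terms
for a declared chromosome set; combinations with an empty joint genotype
cell are skipped with a warning. Missing marker calls exclude an
individual only from models involving that chromosome.

## Pool-seq association scan (`eyemorph.poolgwas`)

Individuals ranked by relative eye size are split into quartiles with the
extremes taking the larger shares first — Q1 and Q4 each get ⌈n/4⌉, the
remainder splits between Q2 and Q3 — reproducing (40, 39, 38, 40) at
n = 157. Ties break by stable sort on input order.

Per pool, a coverage band keeps the central 68.2% of sites: the empirical
quantile interval [0.159, 0.841], rounded to the nearest integers (so the
kept fraction matches the target; outward rounding is available when a
guaranteed-coverage band is preferred). The candidate cascade further
applies a mean ± 3 s.d. coverage mask on parental re-sequencing data and
drops sites with conflicting parental read support (reference-allele
reads in the non-reference parent or alternative-allele reads in the
reference strain; the conservative OR rule by default, AND available).

Association is a two-sided Fisher exact test on the 2×2 ref/alt read-
count table of the two extreme pools, implemented as a vectorized
hypergeometric enumeration (sum of table probabilities not exceeding the
observed table's, with the usual 1e-7 relative tolerance); it matches
`scipy.stats.fisher_exact` to 1e-10 and is fast enough for 10⁵-site
scans. Bonferroni correction uses the number of SNPs actually tested
after coverage filtering; sites with an empty pool are skipped and do not
count. Significant sites then pass a strict directionality filter
(reference allele more frequent in the high pool) and a phylogenetic-
consistency filter (both outgroup strains carry the alternative allele),
and can be intersected exactly — keyed by (chrom, pos, ref, alt) — with
an independently significant set such as a population-differentiation
scan. Allele frequency is ref/(ref+alt) read counts with no pool-size
correction.

A caveat the calibration experiments make explicit: the Fisher test's
null assumes both pools sample one underlying allele frequency. Quartile
pools are *different individuals*, so their true frequencies differ by
individual sampling, and on individual-resampled null data the read-count
test is anti-conservative (a well-known pool-seq overdispersion). The
machinery calibration therefore uses the read-sampling null (same
population frequencies, independent read draws per pool), which the
generator provides as a mode; the block-recovery experiments use the full
individual-resampling design, where the causal signal dominates this
background.

## Annotation and enrichment (`eyemorph.annotate`)

SNP coordinates move between assemblies through colinear alignment
blocks (position arithmetic plus allele complementation on '−' blocks;
unmapped SNPs are reported, not fatal). Gene models come from GFF3/GTF
with the longest isoform per gene. Classification precedence is
exonic > splicing (within 2 bp of an intron boundary) > UTR > intronic >
up/downstream (within a 1,000 bp flank, strand-aware) > intergenic;
coding SNPs are called synonymous/nonsynonymous by codon translation on
the coding strand when genomic sequence is supplied (genes whose CDS
length is not a multiple of 3 are flagged and get the generic exonic
class). With several genes in range the highest-precedence class wins and
all gene ids are reported.

Enrichment is a 2×2 chi-square with Yates continuity correction. Because
published statistics rarely state the exact table construction, two forms
are implemented — "marginal" (k, n−k; K, N−K) and "disjoint"
(k, n−k; K−k, N−n−(K−k)) — and `enrichment_mode_search` evaluates a grid
of (form, genome-total) modes against printed statistics, reporting the
reproducing mode per statistic. The default genome-total grid contains
13,701 and 13,767 (both appear in published usage) plus 13,764
(= 13,767 minus three candidate genes excluded for living on unanchored
scaffolds); gene exclusions of that kind are an explicit input list, not
hard-coded knowledge.

## Ancestral reconstruction (`eyemorph.phylo`)

Brownian-motion ML ancestral states are computed by exact Gaussian
message passing on the rooted tree: an upward (pruning) pass aggregates
tip information into (estimate, variance) messages and a downward pass
adds the information from the rest of the tree; each internal node's
state is the precision-weighted average of its incident messages, which
equals the re-rooted GLS estimator. States are convex combinations of tip
values and invariant to tip order and uniform branch-length rescaling;
reported variances are the GLS conditional variances up to the BM rate.
Squared-change parsimony for shape vectors minimizes the branch-length-
weighted sum of squared changes by solving the tree Laplacian per
coordinate, and equals the BM ML states applied coordinate-wise
(asserted numerically to 1e-10; an unweighted mode is available).
Zero-length branches are replaced by 1e-8 × tree height and logged.
Pruning tips collapses the resulting degree-2 nodes by summing incident
branch lengths, conserving all patristic distances among retained tips.

## Synthetic data (`eyemorph.synthetic`)

All generators are bit-reproducible given (seed, config); each derives an
independent stream from the seed and a generator tag.

**Landmarks.** Specimens are a group mean shape (a head-outline ellipse
plus a group-specific offset along a random unit direction) plus three
fixed unit-norm deformation fields shared by all specimens — pitch,
a "biological" within-group axis, and yaw — with per-specimen Gaussian
scores, plus isotropic digitizing noise, then randomly rotated, scaled
and translated. The fields are mutually orthogonal, orthogonal to the
group-offset directions and to the similarity directions at the base
shape, so alignment cannot absorb them. Default score standard deviations
(pitch 0.05, biological 0.022, yaw 0.01, noise 0.002 per coordinate, on
the unit-centroid-size scale) form a geometrically spaced ladder: the
two-step removal assumes pitch loads on PC1 and yaw on PC3 of the raw
pooled PCA (PC2 after step one), and that structure is only identifiable
with clear eigen-gaps. Two further facts shape the recovery experiments:
the residual correlation between corrected coordinates and true nuisance
scores has a ~1/√n estimation floor (≈0.07 at 100 specimens per group),
so tight correlation bounds are assessed at 600–1,000 specimens per
group, while mean-shape distance recovery is assessed at 100 per group.

**Backcross.** Chromosome genotypes are independent Bernoulli(1/2)
hom/het calls expressed through the study's marker panel (A6/X, B3/4th,
C3+C5/5th, D7+E7/fused 2nd–3rd), with configurable linked-pair
recombinants and donor-homozygote contaminants. The phenotype is
additive: eye area = baseline × (1 + Σ effect·het + noise) + baseline ×
(s²−1), where s is a latent linear body scale (s.d. 0.05) that also
scales tibia lengths (∝ s) and wing area (∝ s²) and is itself shifted by
the chromosomes in `backcross_body_effects` (default: +3% for the 5th).
Defaults plant effects of +4.1%, +3.5% and +2.3% on the 4th, fused
2nd–3rd and 5th chromosomes with residual noise σ = 4.36% of baseline —
the unique noise level that makes the three printed R² values
(0.153, 0.110, 0.048) mutually consistent with those effects at n = 552
under R² = 0.25·Δ²/V.

**F18 pool-seq.** Two founder haplotypes fixed for alternative alleles
found one F1 pair, which founds 50 independent full-sib chains (the
stated census; a single chain would fix ~98% of loci and leave no
mappable variation). Each meiosis deposits Poisson(1) crossovers per
chromosome, suppressed inside declared inversion intervals when the
parent is heterokaryotypic — homokaryotypes recombine freely. After 17
generations the 157 phenotyped females are fresh progeny drawn round-
robin across chains; phenotype is additive in causal-SNP dosage plus
Gaussian noise; quartile pools use the partition rule above; reads are
Binomial(depth, pool frequency) with depth ~ round(Normal(80, 15))
truncated at 1. True per-pool allele counts before read sampling are
recorded and sum to 2 × pool size at every site. The same SNP site
catalog (positions and ref/alt bases) is shared with the population-pool
generator for a given seed so intersection workflows operate on real
keys. What this generator does *not* emulate: selection and drift beyond
the mating design, read-level errors, mapping artifacts, indels, or
linked-variant ascertainment — so passing tests demonstrate the
statistical machinery, not robustness to sequencing artifacts.

**Population pools.** Two pools (southern/northern) with allele
frequencies 0.9/0.1 inside declared inversion intervals and 0.5
elsewhere, sampled binomially through pool allele counts then reads.

**Tree traits.** Brownian motion from a configurable root state along a
5-tip phylad-like default tree; the root state is recorded for
unbiasedness checks.

## Problem sizes used in validation

The automated experiments run at: 20,000 SNPs × 50 replicates for the
null-calibration scan, 20,000 SNPs for block recovery plus 4,000-SNP
power curves at four depths, 200 CVA null replicates at 15 specimens per
group with 199 permutations, 100 backcross replicates at n = 552,
1,000 (correlation) and 100 (distance) specimens per group for the
morphometric recovery, and 200–500 tree replicates. These sizes put
Monte-Carlo error comfortably inside each assertion's tolerance.

## Known limitations

* The Fisher read-count test ignores pool-composition sampling noise, as
  in the original design; the overdispersion subsection above quantifies
  the consequence and the background-significance rate the acceptance
  script reports makes it visible.
* The conservative body-size correction attenuates (by design) any eye
  effect of a chromosome that also moves body size.
* Percent effects are relative to the hom-class mean of relative eye
  size, which absorbs half of the other chromosomes' effects into the
  denominator (a property of the published estimator, reproduced here).
* Semilandmarks are treated as fixed landmarks; no bending-energy
  sliding, no 3D landmarks, no thin-plate-spline visualization.
* No read mapping, SNP calling, Fst/CMH statistics, tree inference, or
  GO-term retrieval; candidate lists, gene models and block maps are file
  inputs.
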