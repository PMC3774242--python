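# Methods

This note documents the statistical models behind `pleiomap`, the
design of the synthetic-data generators, the numerical conventions, and
what the validation experiments do and do not establish.

## RIL genetics and the scan model

**Genotype process.** A selfed recombinant inbred line is homozygous at
essentially every locus, so a line's genome is a mosaic of the two
parental genomes and the genotype along a chromosome is a two-state
process.  We simulate it directly at the RIL scale as a Markov chain:
between adjacent loci d cM apart, the per-meiosis recombination fraction
under a Haldane (no-interference) map is r = (1 − e^(−2d/100))/2, and
the chain switches parental state with the map-expanded probability
R = 2r/(1+2r), the fixed point of recurrent selfing.  Simulating the
chain at the RIL scale is marginally equivalent to simulating the
selfing generations explicitly, is far cheaper, and gives closed-form
oracles (the validation suite checks the observed recombinant fraction
against 2r/(1+2r) at n = 10 000 lines).  Residual F9 heterozygosity
(~0.4% per locus) is ignored by default; `missing_rate` can emulate
het-masked calls.

**Genotype probabilities.** Scanning needs P(parent-A homozygote) at
every point of an even pseudo-marker grid (default step 2 cM, all true
markers retained; each inter-marker gap of size g is split into
⌈g/step⌉ equal pieces).  Probabilities are exact forward–backward
conditionals on the two-state chain, conditioning on the nearest
informative flanking markers; beyond the terminal informative marker a
single-flank transition applies, and a line with no informative marker
on a chromosome falls back to the marginal 0.5 (logged).  The
`map_scale` flag controls whether input map distances are treated as
already on the expanded RIL scale (`ril`, the default — appropriate
when the map was estimated from RIL data, and exactly self-consistent
because the Haldane kernel composes) or as meiotic distances
(`meiotic`, which applies the 2r/(1+2r) expansion).

**Scan statistic.** The profile LOD is the Gaussian-regression form
LOD(x) = (n/2)·log₁₀(RSS₀/RSS₁(x)), from regressing the phenotype on
the expected parent-A dosage at x (Haley–Knott).  We use conditional
expectations rather than a multiple-imputation engine as the default
because the result is deterministic and identical, at fully observed
markers, to ordinary least squares — which the tests exploit as an
algebraic oracle (agreement to 1e-8; observed ~1e-13).  An optional
imputation-mode scan (default 256 draws) is provided for comparison
with imputation-based mapping software; its LODs differ slightly
because independent per-position draws ignore the chain's joint law.

**Permutation threshold.** Experiment-wise significance comes from the
empirical (1 − α) quantile of the genome-wide maximum LOD over random
phenotype permutations (default 1000; the validation experiments use
500 and the pipeline default can be raised to the traditional 10 000).
Calibration is checked by simulation: over 200 pure-noise phenotypes,
the fraction whose own scan exceeds their own threshold must sit inside
the 95% binomial interval around α = 0.05.

**Model selection.** Stepwise search is additive-only: forward steps
add the grid position with the largest LOD gain while the penalized LOD
(model LOD − penalty × n_QTL, penalty = the permutation threshold)
increases, with backward pruning after each step; position refinement
then cycles over the selected QTLs, re-scanning each with the others
held fixed, which cannot decrease the model LOD.  Epistatic scan steps
are deliberately out of scope: the pleiotropic signal this package
targets is additive, and epistatic penalties would dominate the design
for little benefit here.  The final joint fit reports per-QTL allele
substitution effects, percent variance explained from drop-one sums of
squares, and drop-one LODs; collinear dosage columns yield a drop-one
LOD of 0 with a warning.  RSS is floored at 1e-12·RSS₀ so degenerate
perfect fits produce large finite LODs.  Argmax ties resolve to the
lowest (chromosome, position).

## Bivariate co-localization

Each trait's LOD profile is standardized by its genome-wide maximum, so
both peaks equal 1, and the standardized profiles are summed into S(x)
∈ [0, 2].  The joint peak is the argmax of S.  The support interval is
cut by the `peak_fraction` rule (default α = 0.5): the contiguous run
of grid positions around the peak with S(x) ≥ α·S(peak).  α → 1
shrinks the interval to the peak point; lowering α never shrinks it.
A `literal` rule is retained as a documented alternative: it thresholds
S against the position-wise average of the two unstandardized profiles
rescaled to S's maximum.  Read strictly, an "average single-phenotype
score" threshold is S(x)/2, which S(x) exceeds everywhere — degenerate
— so the fraction-of-summit rule is the default and the literal variant
is exposed only for comparison.

Two traits are supported; the container generalizes to T traits but the
interval logic is only exercised for T = 2.

## Class-contrast FST

Accessions are inbred, so genotypes are haploid allele calls
(heterozygous VCF calls are set missing with a warning).  Two per-SNP
estimators:

* **nei** — F_ST = (H_t − H_s)/H_t with H_t = 2p̄(1−p̄) at the
  pooled-sample frequency and H_s the *unweighted* mean of 2p_k(1−p_k)
  over the two classes (recorded in result metadata; unequal class
  sizes can push raw values slightly negative, and raw values are kept).
  Genome-wide: unweighted mean over usable SNPs.
* **wc** — Weir–Cockerham-style variance components adapted to haploid
  samples, θ = (MSA − MSW)/(MSA + (n_c − 1)·MSW); genome-wide
  aggregation is ratio-of-sums by default (mean-of-ratios optional).
  For two demes at equal sizes the two estimators are related by
  θ ≈ 2G/(1+G), which the tests check on simulated panels.

SNPs are skipped (and counted) when monomorphic, when a class has fewer
than two called accessions, or when more than 20% of labeled accessions
are missing (configurable).

**Resampling nulls.** (i) *Class-label permutations*: random divisions
of the accessions preserving the observed class counts; the statistic
is the genome-wide mean FST and the empirical p is (1+b)/(1+K), never
zero (default K = 5000).  (ii) *Frequency-matched SNP partitions*: each
resample partitions the accessions by the alleles of a random SNP whose
minor-allele frequency is within ±0.02 (configurable; no canonical
value exists) of the focal class frequency, and recomputes the mean FST
with the partitioning SNP left out.  Both observed and resampled
statistics go through the same code path so the comparison is exact.

**Regional FST.** Within each geographic cluster, SNPs are thinned
greedily to ≥ 50 kb spacing (first SNP kept, duplicates at one position
collapse to the first), H_t and H_s are averaged over thinned SNPs, and
the cluster FST is the ratio of those averages.  Clusters missing a
class are skipped and reported.

## Functionality imputation

Features are the 0/1 alleles of all SNPs within ±100 kb of the focal
locus (closed interval); missing calls are filled with the SNP's major
allele (the choice is logged; no canonical treatment exists).  The
classifier is an RBF-kernel SVC; the kernel width (gamma) and
regularization (C) are chosen by grid search over a log grid spanning
2⁻⁶…2² × 2⁻²…2⁶ on inner stratified CV, with ties resolved to the
smallest C then the smallest gamma for determinism.  Grid search and
all preprocessing happen strictly inside training splits; the
label-permutation control (CV accuracy within binomial range of the
majority baseline) is the leakage test.

Two protocols: stratified k-fold (default fourfold), and repeated
leave-one-out CV on random size-n subsets (single-class draws redrawn,
up to 100 attempts; inner folds degrade gracefully when a class is
tiny, down to fixed mid-grid hyperparameters when inner CV is
infeasible).  Decision threshold is margin 0 — binary binning is all
the pipeline needs downstream — and imputed accessions carry their
decision-function margin; accessions with no window data stay unknown
and are excluded downstream.

## Association statistics

GR_la = [ln(LA_t2) − ln(LA_t1)]/(t2 − t1) per day.  One-way
fixed-effects ANOVA with PVE = SSB/SST × 100 (the SST = SSB + SSW
identity is tested to 1e-10, and F equals the squared pooled-variance t
for two groups).  Trait–trait correlation is Pearson r² on
pairwise-complete line means with the two-sided t-transform p.  Climate
associations use Welch t-tests (the unequal-variance form; the variant
is otherwise unspecified in this literature) with Bonferroni adjustment
over the 19-variable family and flags at adjusted p < 0.05.  Rank
summaries report each class's mean pooled rank normalized by N + 1, so
identical classes sit at 0.5 and complete separation approaches
0.25/0.75 at equal sizes.

## The synthetic-data generators

**RIL cross (`RILSimConfig`).** Defaults: 343 lines, five ~85 cM
chromosomes carrying 166 markers in total, one pleiotropic QTL at
(chromosome 4, 4.0 cM) whose effects give ~25% and ~15% of the two
traits' variance, one ~8% trait-specific QTL per trait, unit residual
SD, and residual cross-trait correlation 0.25 — which, combined with
the shared QTL, puts the line-mean WUE–FT correlation near r² ≈ 0.13,
the level reported for this kind of cross.  Phenotypes are QTL effects
on centered genotypes + optional polygenic term (random marker weights,
normalized) + correlated Gaussian residuals.  Leaf areas at days 14 and
21 are generated from a growth rate that shares the main QTL, so the
GR_la stage has signal.  `additive_effect_for_pve` converts a target
variance fraction into a substitution effect (a = 2√(pve/(1−pve)·V_bg)
at allele frequency ½).

**Accession panel (`PanelSimConfig`).** Defaults: 317 accessions,
functionality frequency 0.5 (both strategies common, as in broad
geographic samples), focal locus at chromosome 4 : 270 kb, 50 window
SNPs within ±100 kb, 10 000 genome SNPs at ~1 kb spacing over five
chromosomes, target between-class Nei FST 0.05, 11 geographic clusters,
19 climate variables shifted 0.5 SD between classes.

*Window LD.* Window SNPs tag the focal allele through one shared latent
haplotype: the haplotype copies the label with probability b, each SNP
copies the haplotype with probability a, otherwise an independent draw
at the focal frequency (preserving allele frequencies), and
a = b = (tag_ld_r2)^¼ gives every SNP its requested squared correlation
with the label.  The latent layer matters: conditionally independent
tags would let a classifier reach 100% accuracy from a handful of
accessions, whereas real LD blocks share one recombination history and
cap what any number of window SNPs can reveal.  With the default
tag_ld_r2 = 0.5 the haplotype→label fidelity is ≈ 0.92, and the
subset-LOOCV accuracy rises from ≈ 0.84 at n = 10 through ≈ 0.92 at
n = 20 toward that ceiling — the qualitative small-sample learnability
profile reported for this kind of imputation (87% at n = 10, 93% by
n = 20, ~95% in fourfold CV on the full labeled panel).

*Genome-wide differentiation.* Each genome SNP gets a base frequency
p ~ U(0.25, 0.75) and symmetric class frequencies p ± δ with
δ = √(FST·p(1−p)), which hits the target Nei FST exactly at the
population level (FST = δ²/(p(1−p)) under the unweighted H_s); δ that
would leave [0, 1] is truncated to the boundary and the SNP flagged in
the truth record (never triggered in the default frequency range for
FST ≤ 1/3).  Climate variables are independent Gaussians given class —
the simplest structure satisfying the t-test stage's assumptions.

Every dataset ships with a `TruthRecord` (QTLs, labels, window SNP
indices, truncated SNPs, climate shifts) that round-trips through JSON.

**What the generators do not emulate.** Coalescent haplotype structure,
isolation by distance, selection, linkage between the focal locus and
the genome-wide SNP background, spatially autocorrelated climate, and
label noise in the training panel.  Passing tests therefore demonstrate
that the estimators and protocols are correct and calibrated under
their stated assumptions — not that real panels satisfy those
assumptions.

## Validation experiment sizes

The experiments in `pleiomap.experiments` (run by the test suite and by
`scripts/acceptance.py`) use desk-scale sizes chosen for precision per
unit cost: map expansion at 10 000 lines; threshold calibration over
200 null phenotypes × 500 permutations; QTL recovery over 100 replicate
343-line crosses (shared QTL, PVE 25%/15%, detection + 5 cM
localization + interval coverage); FST recovery over 50 000 SNPs at
target 0.2 with permutation-floor and 200-replicate null calibration;
the CV trend over 8 independent panels × 20 subset draws per size with
a compact 3×3 hyperparameter grid (the full grid adds cost but not
information at these subset sizes).  Resampling counts are scaled down
from the traditional 10 000/5 000 used on real data; all experiments
are seed-deterministic.

## Known limitations

* Additive QTL models only; no epistatic scan or covariates.
* Two traits in the bivariate statistic.
* The imputation-mode scan draws genotypes independently per position —
  adequate for cross-checking LOD levels, not a full imputation engine.
* The Weir–Cockerham form is the haploid two-population reduction;
  multi-population θ is out of scope.
* VCF support is the minimal biallelic GT subset (haploid or
  homozygous-diploid calls); no compressed/indexed VCF handling.
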