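# Methods

`pairedcn` implements a complete shallow-WGS copy-number analysis for
paired diagnosis/relapse tumour cohorts: binned read counts → relative
copy number → segmentation → absolute copy number (purity/ploidy) →
copy-number signature exposures, intra-tumour heterogeneity, paired
genome subtraction, focal gene events and compositional group tests. A
synthetic cohort generator provides ground truth for every stage, so the
whole chain is testable without access-controlled patient data.

## The count model

A sample is a mixture of tumour cells (fraction ρ, the purity) and
diploid non-tumour cells. For a bin with tumour copy number n, the
expected read count is

    μ = depth · [ρ·n + 2(1−ρ)] / [ρ·ψ + 2(1−ρ)] · g(GC) · m^e

where ψ is the tumour ploidy (length-weighted mean tumour copy number),
g a quadratic GC bias curve and m the bin's mappability. Counts are
Poisson by default; a negative-binomial option (Var = μ + φμ²) covers
overdispersed libraries. `depth` defaults to 60 reads per bin — 0.1×
coverage of 30 kb bins with 50 bp single-end reads (0.1·30000/50).
All intervals in the package are 0-based, half-open (BED convention).

The simulated per-bin GC track varies mostly bin to bin (as real 30 kb
GC content does). This matters: a GC track as smooth as the segment
structure is confounded with copy number within a single genome, and no
within-sample correction can separate them.

## Bias correction

Counts are corrected by quantile-binned medians in GC, then in
mappability. The factors are estimated from counts pre-normalised by
their chromosome's median count (a coarse copy-number proxy). Without
that proxy step, a genome of widely separated copy levels makes the
count distribution within each GC quantile multimodal; its median then
jumps between levels and the "correction" distorts the profile. Bins
with mappability < 0.5 are masked throughout. The corrected profile is
median-normalised to 1.

Quantile-median fits were chosen over LOESS for determinism and
robustness; with 20 GC × 10 mappability bins over ≥10⁴ bins each factor
is estimated from hundreds of observations.

## Segmentation

Piecewise-constant fitting uses exact penalized optimal partitioning
with PELT pruning under an L2 cost, written in-house (no changepoint
library is a dependency). Detection runs per chromosome on √ratio: at
~0.1× counts are near-Poisson, so the square root stabilises the
variance across copy states, whereas log2 noise explodes in low-copy
regions and produces spurious breakpoints exactly where deletions live.
Reported segment values are linear-scale means of member bins.

The default penalty is 4·σ̂²·log n per chromosome, with σ̂ a robust
(MAD-of-differences) noise scale. The multiplier sits above the
asymptotic BIC value of 2 deliberately: bias-correction residuals add
structured noise the difference-based estimator underestimates, and a
false breakpoint corrupts every downstream feature while a missed sub-Mb
single-copy event costs little. A noiseless step signal is still
recovered exactly (the penalty floors at 10⁻⁸, never 0).

## Absolute copy number

The mixture model inverts as

    n = ( r·[ρψ + 2(1−ρ)] − 2(1−ρ) ) / ρ

with r relative copy number on the scale where its length-weighted
genome mean is 1 (the fitter rescales internally; the median-normalised
input scale differs from the mean scale whenever the genome is skewed).

Purity and ploidy are fitted by grid search, ρ ∈ [0.20, 1.00] and
ψ ∈ [1.6, 8.0] both in 0.05 steps, minimising the length-weighted mean
squared distance of transformed segment values to the nearest
non-negative integer.

**Identifiability and tie handling.** Absolute copy number from coverage
alone is identifiable only up to affine lattice maps: shifting every
state by +c is an exact alternative fit at purity 2ρ/(2−cρ) and ploidy
ψ+c, and doubling maps ψ to 2ψ. With noise these alternatives score
within the noise floor of the truth. The fitter therefore treats all
grid points scoring within a relative band of the minimum
(score ≤ best·1.5) as statistically equivalent and reports the most
parsimonious: lowest ploidy first, then highest purity. The truth is
recovered whenever the genome anchors the lattice — a homozygous-
deletion (state 0) segment blocks downshifts, and any odd state blocks
halving. HGSC genomes essentially always carry such anchors. For
noiseless profiles the band collapses and only exact ties compete; the
recovery suite (120 noiseless profiles across ρ ∈ {0.3,…,1.0},
ψ ∈ {2,3,4}, ≥5 states, state-0 anchor) recovers 100% within one grid
step.

QC: a fit passes if the goodness-of-fit score is ≤ 0.05 and ≥ 50% of the
genome lies within 0.3 of an integer state; both thresholds are
configurable. Ploidy change between paired samples is called when
|ψ̂_rel − ψ̂_dx| exceeds 0.5 copies (configurable).

## Copy-number signatures

Six per-sample feature distributions are extracted from the absolute
profile: segment size (Mb), breakpoint count per tiled 10 Mb window,
change-point magnitude at adjacent segments, segment copy state (rounded,
capped at 10), breakpoint count per chromosome arm, and the lengths of
oscillating chains (maximal runs of ≥ 3 segments alternating between
exactly two states). Each feature value is scored against a fixed
mixture component model (Gaussian or Poisson components); the sample
encoding is the component-wise sum of posterior probabilities. Exposures
to seven signatures are the non-negative least-squares solution of the
normalised encoding against a column-stochastic definitions matrix,
renormalised to the simplex.

The published component model and signature definitions are external
inputs the package reads from file. The bundled stand-ins are synthetic:
a 29-component model spanning the value ranges the event generator
produces (including chromosome-scale segment sizes), and definitions
calibrated by Monte Carlo — pure one-class genomes simulated, features
extracted, encodings averaged per class. NNLS exposures measure
*feature-mass* shares; event classes differ up to ~8× in feature mass
per event, so recovery analyses convert to event-count shares using the
per-class mass factors the same calibration returns.

**Known limitation.** At ~0.1× coverage the chain counts → fit →
features → exposures is information-limited: purity/ploidy lattice noise
and segmentation variance, amplified by the ill-conditioned definitions
matrix (condition number ≈ 30–40), attenuate per-cohort rank correlation
between simulated and estimated dominant exposures to ≈ 0.3–0.7
depending on the random cohort. From true segmentations the same
statistic is ≈ 0.87. Decomposition in isolation is accurate (exact
mixtures to 10⁻⁶, noisy mixtures to MAE < 0.05). Passing tests therefore
demonstrate correctness of each stage and positive end-to-end signal
flow — not that 0.1× sWGS determines exposures precisely, which it does
not without the fit curation real studies apply.

## Intra-tumour heterogeneity

ITH is the length-weighted mean distance of segment copy numbers from
the nearest non-negative integer: 0 for a clonal integer genome, at most
0.5. Weights are bp (masked bins never reach the segment table). Exact
half-integers report the lower state (the distance is 0.5 either way).
The formula is verified against a brute-force per-bin average to 10⁻⁹.
ΔITH is relapse ITH minus diagnosis ITH per patient.

## Cohort statistics

*Genome-wide subtraction*: per bin, a two-sided Mann–Whitney U test of
diagnosis vs relapse absolute copy number across patients, with
Benjamini–Hochberg correction applied within each chromosome; the
reported profile is median(relapse) − median(diagnosis), positive values
meaning gain at relapse. Patients missing a bin are dropped bin-wise.
All-tied bins get p = 1.

*Focal gene events*: gene copy number is the length-weighted mean of
overlapping segments; amplified iff CN ≥ max(5, 2ψ̂); deleted iff
CN ≤ max(ψ̂ − 1.87, 0) (a sub-single-copy loss). Both thresholds are
config-overridable so users can match any published supplementary rule.
Group comparisons are two-sided Fisher exact tests per gene with BH
adjustment across the gene family. The bundled 18-gene panel uses the
field's usual HGSC gene names at synthetic coordinates on the toy
genome; real analyses supply their own interval BED.

*Per-signature univariate tests*: Mann–Whitney U (unpaired) or Wilcoxon
signed-rank (paired) per signature, unadjusted by default (BH optional).

*Exposure–immune correlations*: Kendall τ and Spearman ρ per
(signature, marker, compartment), unadjusted; constant vectors are
reported as missing.

## Compositional differential abundance

Exposures live on the simplex, so group comparisons use pivot-coordinate
ILR: z = Vᵀ ln x with V the orthonormal pivot basis, inverse
x = softmax(Vz). Zeros are handled by multiplicative replacement
(parts < ε = 10⁻³ floored at ε, remainder rescaled; ε configurable).
Excluding a signature (e.g. a fixation-artefact signature) renormalises
the subcomposition before the transform.

Per ILR coordinate a linear mixed model with fixed group effect and
random patient intercept is fitted; the global test statistic is the sum
of squared slope z-scores against a χ² with one degree of freedom per
coordinate. For the balanced paired design (every patient exactly one
sample per group) the GLS solution is closed-form — the slope is the
mean within-patient difference with its empirical standard error — and
the model uses it directly; unbalanced designs go through an iterative
mixed-model fit (OLS fallback, with a recorded warning, when the random
effect is unidentifiable, including the one-sample-per-patient case).
Calibration measured under the within-patient permutation null (47
pairs, 500 permutations): type-I error 0.05–0.07 at α = 0.05; power 1.0
for a 0.15 absolute planted shift in one signature. Group composition
summaries are the inverse ILR of the fitted intercepts and of
intercepts + slopes — geometric-mean compositions, not arithmetic means.

## The synthetic cohort: what it emulates, and what not

Each patient receives a latent signature composition
(Dirichlet(1.5) over 7 signatures); diagnosis and relapse exposures are
centred log-ratio jitters (σ = 0.15) of it. Genomes start flat at
baseline ploidy 2 (25% of patients tetraploid) and receive 10 events on
the 300 Mb toy genome (scaled to genome length; ~60 on the hg-scale
layout), each event's class drawn from the exposure vector: large
interstitial segments, whole arms, focal amplifications, focal
deletions, oscillating chains, chromothripsis-like shattering, whole
chromosomes. Losses clip at zero. Purity is Uniform(0.35, 0.95).
Clinical labels follow the platinum rule (resistant iff relapse interval
< 6 months; sensitive fraction 0.76, primary-resistant 0.09,
BRCA-mutant 0.19). Relapse genomes equal diagnosis genomes by default;
perturbations plant a copy-number region or a whole-genome doubling.

Not emulated: replication-timing and fragmentation biases beyond GC and
mappability, subclonal (non-integer) tumour populations, multi-biopsy
patients (one sample per role; more are a configuration concern), FFPE
artefact structure, and allele-specific signal (LOH is invisible to
coverage-only sWGS). Tests passing on this generator therefore validate
the pipeline's mathematics and calibration, not robustness to every
artefact of archival clinical material.

## Problem sizes

The default test genome is the 3-chromosome, 300 Mb toy layout (10,000
bins of 30 kb); signature-recovery integration tests use the hg-scale
22-autosome layout where the arm-level features have their full sample
size. Cohort-level checks use 20–47 pairs, matching the scale of paired
high-quality cohorts in this setting. The full test suite runs in a few
minutes on one CPU; `scripts/acceptance.py` in roughly one.
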