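# Methods

This note documents the models, the numerical choices and the synthetic
data behind `ptctools`, in the spirit of a statistical-software methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Enhancer-interaction models

Two enhancers of one gene are encoded by binary indicators x₁, x₂
(1 = intact, 0 = excised), so the wild type is (1, 1) and the double
knockout (0, 0) is the intercept baseline. Raw expression (RT-qPCR-style,
arbitrary units) is first divided by the mean wild-type value of its own
experimental batch; this cancels multiplicative batch effects and fixes
the WT mean at 1. Normalization is idempotent and requires at least one
positive-mean WT measurement per batch.

Three mean structures are fitted under additive Gaussian noise with
constant variance:

| family | mean μ(x₁, x₂) | free parameters |
| --- | --- | --- |
| additive | b₀ + b₁x₁ + b₂x₂ | b₀, b₁, b₂, σ (4) |
| exponential | exp(b₀ + b₁x₁ + b₂x₂) | b₀, b₁, b₂, σ (4) |
| logistic | g / (1 + e^−(b₀+b₁x₁+b₂x₂)) | g, b₀, b₁, b₂, σ (5) |

The noise model is a deliberate choice: the experimental description of the
error term ("biological and technical noise") does not pin down a family,
and normalized qPCR replicates at modest fold-changes are adequately
described as homoskedastic Gaussian. σ is profiled by maximum likelihood
(σ̂² = RSS/n) and counted as a free parameter in
BIC = k·ln(n) − 2·ln(L̂). ΔBIC is reported against the additive fit as the
reference, and every family whose BIC is within `threshold` (default 2) of
the minimum is reported as jointly best — a difference below 2 is not
treated as decisive, so ties are surfaced rather than forced to a winner.

Optimization: the additive optimum is the closed-form least-squares
solution. The exponential family is initialized from a log-linear
regression on the genotype group means (falling back to a zero start when
a group mean is non-positive) and refined by Levenberg–Marquardt; the
logistic family is initialized with g = 1.05·max(y) and a logit-linear
regression of the group means, refined by bounded trust-region least
squares. Both get 10 seeded random restarts with a short iteration budget
each, and the winning start is polished to tolerance 1e-8 on the
objective; the result is deterministic given data and seed. The logistic
ceiling is bounded at g ≤ 10³·max(y): when the data are exactly
log-additive the logistic likelihood increases monotonically as
g → ∞ toward the exponential fit, and the cap keeps the optimizer finite
without constraining any realistic saturation level (at the cap the two
mean structures differ by < 0.1%). On noise-free data σ̂ is floored at
1e-12 so the log-likelihood stays finite.

Predictive bands are Gaussian quantiles N(μ̂, σ̂²); coefficient reports
include b₁/b₂ (flagged undefined when b₂ = 0) and an
activator/antagonist flag from the coefficient sign.

## Image colocalization

The pipeline quantifies whether an immunofluorescence signal (e.g. the
condensate component BRD4) is enriched at a FISH-labelled locus, from
3-channel z-stacks with intensities in [0, 1].

1. *Nuclei.* Each DAPI slice is smoothed with a 31×31 truncated Gaussian
   brush (σ = 5, implemented as a separable `scipy.ndimage.gaussian_filter`
   with truncate = 15/5, kernel normalized to sum 1), and the smoothed
   stack is thresholded with a single Otsu cutoff computed over the whole
   stack. A stack-global threshold (rather than per slice) keeps slices
   above and below the nuclei — which contain only noise — empty; holes
   are filled per slice. Nuclei touching the image border are kept but
   flagged.
2. *Spots.* Each FISH slice is smoothed with a 9×9 brush (σ = 5) and cut
   at a fixed threshold. The threshold is a free parameter (chosen by eye
   on real data); the default heuristic is mean + 6·SD of the smoothed
   channel. Connected components with any pixel outside a nucleus are
   discarded entirely; nuclei without spots are dropped.
3. *Centers.* The moment centroid of each spot region is shifted to the
   brightest FISH pixel of the region; ties break to the smallest
   (row, col).
4. *Stitching.* Nuclei and spots are linked across adjacent slices when
   their 2D footprints share at least one pixel (implemented as 3D
   labelling with 8-connectivity in-plane and face-connectivity in z).
   The overlap rule is a package decision; one identifier per 3D object
   guarantees each physical spot is counted once.
5. *Null centers.* 50 voxels per nucleus are drawn uniformly *with
   replacement* from the nucleus volume — replacement because the
   requested number of centers may exceed small nuclei's voxel counts.
6. *Windows.* 11×11 IF windows are read around every genuine center (one
   per slice the spot spans, then averaged over valid entries) and every
   random center. Positions outside the nuclear volume or image bounds
   carry value 0 and a validity flag 0 and are excluded from every
   aggregate. Per window position, the median over genuine spots divided
   by the median over random centers gives the enrichment-ratio map; the
   central 3×3 mean summarizes it.
7. *Profile.* FISH/IF pixel pairs from the genuine windows are split into
   20 FISH-quantile (5%-percentile) bins; the per-bin median IF versus bin
   index is scored by Spearman rank correlation. Because no specific test
   accompanies the published "significant correlation" statement, the
   significance here is a package decision: a permutation p-value from
   10⁴ seeded shuffles of the IF values against the FISH values (two-sided
   on |ρ|, with the +1 correction).

The pipeline output is invariant under joint rescaling of the FISH channel
and the detection threshold, and `allocate_random_centers` is
bit-reproducible given its seed.

## Genome-category statistics

Segments scored for enhancer content carry an enrichment p-value, a log2
fold-change and a 3D-hub flag, and are classified: p ≤ 0.05 & log2FC ≥ 0
→ PTC if hub else very active; p > 0.05 → moderately active if
log2FC ≥ 0 else inactive. The cell p ≤ 0.05 & log2FC < 0 (significant
*depletion*) is not covered by the four published rules and is flagged
`unclassified_depleted` instead of being silently binned.

*TF-target enrichment* is observed/expected with
expected = (|targets| / |universe|) · (genes in category); the
category-count-weighted mean score per TF is exactly 1 by construction,
which the tests assert as a conservation check.

*Tissue specificity* of a gene is the fraction of non-focal tissues whose
expression rank (higher expression → numerically higher rank, replicate
columns rank-averaged) is strictly below the focal tissue's rank. The
denominator excludes the focal tissue so the score attains exactly 0 and 1
at the extremes — the reading forced by the published 0–1 range; ties
count as not lower.

*SNP enrichment* shuffles the category intervals across the genome
(length preserved, chromosome drawn proportionally to length among those
long enough, start uniform, inter-interval overlap allowed — the defaults
of the standard shuffle tool), counts SNPs (0-based points,
start ≤ p < end) covered by at least one interval, and reports
observed / mean(permuted) over 100 permutations. Because shuffled
intervals may overlap, the null's expected unique coverage is
1 − exp(−c) rather than the summed coverage c, so at coverage c ≈ 0.1 the
estimator carries a small (~+4%) upward bias relative to the naive
density-ratio expectation; this is inherent to the shuffle-based null, not
a defect of the implementation. A zero mean permuted overlap yields an
undefined (NaN) enrichment flag, not an exception.

*Module overlap* is the upper-tail hypergeometric probability of at least
the observed overlap (`scipy.stats.hypergeom.sf(k−1, N, K, n)`).

## PTC genes

Genes are kept when protein-coding, mean TPM strictly > 1 across the three
timepoints, an H3K27ac peak lies within the closed window ±1000 bp of the
TSS (the promoter anchor is taken as the TSS point; a half-open peak
starting exactly 1000 bp downstream still touches the window edge and
counts), and the gene belongs to a PTC at ≥ 1 timepoint. Membership by
gene-body/segment overlap uses any-overlap, for symmetry with the peak
rule. The seven membership clusters (Invariant, Early, Early-Intermediate,
Intermediate, Intermediate-Late, Late, Early-Late) partition the non-zero
flag triples. Day-0-relative expression divides variance-stabilised counts
by the gene's Day 0 value after excluding genes below a floor (default 1
on that scale — "very low" is not quantified upstream, so the floor is
configurable) at any timepoint.

## Synthetic data

The generators define the reference conditions the tests and the
acceptance script run at:

- *Expression*: four genotypes × 6 replicates by default, noise
  σ = 5% of the WT mean, drawn from the chosen family; batch noise scales
  with the batch factor so WT-normalization removes batch structure
  exactly. Reference coefficient sets: additive (0.2, 0.5, 0.3),
  exponential (0, 1.2, 0.8), logistic (g = 2, −1, 2, 1).
- *Images*: 9×512×512 stacks with 20 ellipsoidal nuclei (in-plane radius
  20–28 px, ≥ 20 px apart so smoothing cannot bridge them), 2 spots per
  nucleus (in-plane σ 1.5 px, spanning ~3 slices, placed well inside the
  nucleus), flat IF background 0.25 with an optional colocalized Gaussian
  at spot centers, additive Gaussian noise clipped to [0, 1]. The spot SNR
  is amplitude/noise-SD. The frame is half the linear size of a typical
  1024×1024 confocal acquisition — the package's choice of reference
  problem size; geometry, not scale, drives every pipeline step.
- *Genomes*: 3 chromosomes × 10 Mb tiled into ~200 segments with category
  mixing defaulting to the 5.5 / 2.5 / 17.8 / 74.2% genome fractions
  observed for PTC / very active / moderately active / inactive in the
  transdifferentiation system, (p, log2FC, hub) triples drawn consistently
  with each category; planted SNP densities (ratio r means r× the
  genome-average per-bp density inside the target category, so the
  analytic enrichment equals r), TF-target bias, and a focal-tissue
  expression shift. Small enough for exact brute-force overlap oracles.

What the fixtures do *not* emulate: optical aberrations, uneven
illumination, nucleus clumping and real chromatin texture in images;
sequence content, assembly gaps/blacklists, LD structure and GC/length
confounding in genomes; heteroskedastic or heavy-tailed qPCR noise.
Passing tests therefore demonstrate correctness of the algorithms under
their stated assumptions, not robustness to every artefact of real data.

## Known limitations

- The two-enhancer design is fixed; the model family generalizes to more
  enhancers but this package does not.
- Interval shuffling is genome-wide and unrestricted (no exclusion
  regions, chromosome of origin not preserved) — matched-permutation
  schemes are out of scope.
- The FISH detection threshold on real data remains a manual choice; only
  the mean + 6·SD default is exercised by tests.
- The logistic fit is reported at the g-cap when the data cannot identify
  a finite ceiling; its BIC is then effectively the exponential fit's
  plus one parameter penalty.
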