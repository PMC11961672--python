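# ptctools

Analysis toolkit for studying how pairs of enhancers inside large 3D
enhancer clusters — putative transcriptional condensates (PTCs) — control
gene expression, whether condensate markers such as BRD4 physically
colocalize with those loci, and how PTC-like genome categories differ from
the rest of the genome. It is aimed at regulatory-genomics groups running
CRISPR enhancer-excision experiments, DNA-FISH/immunofluorescence imaging,
and interval-level genome annotation, and at anyone who wants the
corresponding statistics reproducible on synthetic data.

## What it computes

**Enhancer-interaction models.** Expression of a gene with two enhancers in
states x₁, x₂ ∈ {0, 1} (1 = intact, 0 = excised), measured across the four
CRISPR genotypes and normalized per batch to the wild-type mean, is fitted
by maximum likelihood under three mean structures with Gaussian noise ε:

- additive: E = b₀ + b₁x₁ + b₂x₂ + ε  (independent, linear contributions)
- exponential: E = exp(b₀ + b₁x₁ + b₂x₂) + ε  (multiplicative synergy or,
  with a negative coefficient, antagonism)
- logistic: E = g / (1 + e^−(b₀ + b₁x₁ + b₂x₂)) + ε  (each enhancer lowers
  an energy threshold gating transcription; g is the expression ceiling)

Families are compared by BIC = k·ln(n) − 2·ln(L); every family within 2 BIC
units of the minimum is reported as jointly best. Coefficients b₁, b₂
quantify enhancer potency, their ratio compares the two enhancers, and a
negative sign flags an antagonist.

**DNA-FISH / IF colocalization.** From 3-channel confocal z-stacks
(DAPI / FISH / IF): nucleus segmentation (31×31 Gaussian brush, σ = 5,
Otsu, hole filling), FISH spot detection (9×9 brush, σ = 5, intensity
cutoff, spots outside nuclei discarded), brightest-pixel center
refinement, 3D stitching of nuclei and spots, 50 random in-nucleus centers
per nucleus as the background null, 11×11 IF windows with validity flags,
median enrichment-ratio maps (genuine / random), and a 5%-percentile
binned FISH-vs-IF intensity profile scored by Spearman correlation with a
permutation p-value.

**Genome-category statistics.** Four-way segment classification
(PTC / very active / moderately active / inactive from enrichment p,
log2FC and a 3D-hub flag), TF-target observed/expected enrichment,
a rank-based tissue-specificity score in [0, 1], permutation
(interval-shuffling) SNP-overlap enrichment, and a hypergeometric gene-set
overlap test — plus PTC gene filtering (protein-coding, mean TPM > 1,
H3K27ac peak within ±1 kb of the TSS), the seven-way membership clustering
over three timepoints, and Day-0-relative expression summaries.

**Synthetic data.** `ptctools.simulate` generates expression tables, image
stacks and toy genomes with planted ground truth for every stage.

## Worked example

```python
from ptctools import simulate, enhancer_models as em

raw = simulate.gen_expression_dataset("exponential", b0=0.0, b1=1.2, b2=0.8,
                                      sigma=0.37, reps_per_genotype=6,
                                      batch_scales={"b1": 1.0, "b2": 2.5}, seed=1)
data = em.normalize_to_wt(raw)
fits = em.fit_all_models(data, seed=0)
sel = em.select_models(fits, threshold=2.0)
print(sorted(sel.best_set))
print({m: round(d, 1) for m, d in sel.delta_bic.items()})
print(round(fits["exponential"].b1 / fits["exponential"].b2, 2))
```

prints

```
['exponential']
{'additive': 0.0, 'exponential': -87.3, 'logistic': -83.4}
1.7
```

i.e. the multiplicative model beats the additive reference by ~87 BIC
units and remains ~4 units ahead of the logistic fit (which mimics it at a
large ceiling g but pays for its extra parameter), and enhancer 1 is
fitted ~1.7× as strong as enhancer 2 at this noise level (generating
ratio 1.2/0.8 = 1.5). The same analysis is available from the shell:

```bash
ptctools simulate expression --seed 1 --out run/
ptctools fit-enhancers --input run/expression.tsv --threshold 2 --seed 0 --out run/report.json
```

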