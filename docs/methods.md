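# Methods

## Estimators

**X:AA.** Within one context (a tissue, a tissue+stage, or an explicit
sample set) a gene's expression is its mean FPKM over the selected samples.
After filtering at a cutoff (strictly greater-than; the conventional filter
is FPKM > 1, the "zero" cutoff retains FPKM > 0, and an all-genes sentinel
applies no filter), the point estimate is the **ratio of means**:
mean(X-linked) / mean(autosomal). The ratio-of-means and the mean of
per-gene ratios differ under skew; the former is used throughout and tests
enforce it. "Unexpressed" always means value ≤ cutoff, so a gene at exactly
the cutoff is unexpressed — one consistent convention covering both the
filter and the unexpressed-fraction analysis.

Uncertainty: 1000 bootstrap replicates, each drawing **without replacement**
a set of autosomal genes equal in size to the filtered X set and recomputing
mean(X)/mean(sampled A). The X set is held fixed — the interval describes
the sampling variability of the autosomal reference, not of the X mean. CI
bounds are nearest-rank percentiles (the ⌈p·n⌉-th smallest replicate), which
makes results bit-reproducible; at level 0.90 the bounds are the 0.05 and
0.95 empirical quantiles. A consequence of subsampling without replacement
is the finite-population factor (N−n)/(N−1) on replicate variance: widening
the autosomal pool at fixed n_x *widens* the interval toward the
with-replacement limit (a `with_replacement` flag exists for sensitivity
runs). Because only the autosomal side is resampled, the nominal 90%
interval covers a simulated ground truth slightly below nominal (≈86–89%
observed over 100 runs) — inherent to the error-bar definition, not a
defect of the implementation.

**X:XX.** Pipeline order is fixed: classify pairs → attach per-context
values → filter → scale → normalize → median.

- *Classification*: an X_pair needs the focal gene on X and the ortholog on
  an allowed outgroup chromosome (e.g. {1, 4} for a chicken-like outgroup;
  an empty set means any outgroup autosome). An AA_pair needs a focal
  autosomal gene and an ortholog off the outgroup's sex chromosomes. A
  marsupial-style rule can treat the outgroup X as an ordinary autosome,
  since the marsupial X is itself fully compensated.
- *Filter*: both members of a pair must exceed the cutoff — only expressed
  genes need compensating, and the X carries more silent genes, so a
  one-sided filter would bias the comparison.
- *Scale*: outgroup values are multiplied by s = median(focal)/
  median(outgroup) over all retained pairs, X and AA pooled. Pooling vs
  AA-only scaling is immaterial because of the next step (a test asserts
  this).
- *Normalize + median*: per-pair ratios focal/outgroup are normalized so the
  AA-pair median is exactly 1, and X:XX is the median over X pairs. Medians
  are equivariant under positive scaling, so the class medians are
  normalized directly rather than every pair ratio — this keeps AA:AA at
  exactly 1.0 in floating point for even pair counts too.

Per-tissue X:XX values use per-tissue scaling factors (each tissue scaled
independently); a global factor can be emulated by passing pooled contexts.

**τ specificity.** τ = Σᵢ(1 − aᵢ)/(n − 1), aᵢ = xᵢ/max(xᵢ), over tissue
profiles of stage-averaged FPKM, or over stage profiles within one tissue.
All-zero profiles are excluded; no log transform is applied by default (raw
mean FPKM), since that is the convention for this index here; tissues
sample different numbers of stages, so stage-τ values are not comparable
across tissues. Tissue-specific genes are defined as τ > 0.8, assigned to
their maximum-expression tissue (ties broken by sorted tissue order and
flagged). The 0.8 threshold is the conventional one and is a parameter.

**Stage dynamics.** Per gene, Spearman ρ between expression and stage rank;
replicates within a stage share a rank and ties take average ranks.
P-values are exact permutation probabilities for n ≤ 9 samples (the null
distribution depends only on the two rank multisets, so it is cached and
shared across all untied genes of a tissue) and the t-approximation above
that. Classes: positive ρ > 0.8 & p < 0.05, negative ρ < −0.8 & p < 0.05;
no multiple-testing correction by default (raw p is the conventional
screen; Benjamini–Hochberg is available). The threshold sweep reports the
X-linked share among *classified* genes (the alternative denominator — all
genes per chromosome — is one flag away) against the X share among all
scored genes as baseline.

**Fisher's exact test** is computed with integer hypergeometric weights:
the two-sided p sums P(k) over the support where the weight is ≤ the
observed table's weight. Integer comparison makes probability ties exact,
with no float tolerance; scipy's implementation serves as an independent
cross-check in the tests, never as the implementation.

**Proteome bins.** X-linked and autosomal abundances are separately sorted
descending (ties broken by gene id), split into 100 contiguous bins of
near-equal size (remainder to the front bins), and the top 25 bins compared
pairwise by ratio of bin means; the summary is the median over the 25
ratios (mean available by flag). The per-dataset summary is unbiased but
noisy on heavy-tailed abundances (per-dataset SD ≈ 0.1 at 200 X genes), so
the acceptance script averages it over 10 replicate datasets. Rank-sum
comparisons use exact labeling enumeration on midranks when both samples
have ≤ 10 values, the tie-corrected normal approximation otherwise.

**Chromatin states.** Promoters are [TSS − 2000, TSS + 1000) on the +
strand and the strand-reflected window [TSS − 999, TSS + 2001) on the −
strand (the TSS base belongs to the downstream side on both strands),
clipped at 0. A state annotates a promoter iff their overlap is ≥ 1 bp
(configurable). Because segmentations are disjoint and sorted per
chromosome, intersection is a binary search, checked against a per-base
brute-force oracle in the tests. A gene's diversity score is its number of
*distinct* states across the union of all epigenomes (per-epigenome sums
are the flagged alternative); per-chromosome state base fractions sum to 1
by construction.

## Synthetic data

The generator is the package's verification substrate. Expression is
log-normal (baseline log-mean log 10 ≈ a 10-FPKM median gene, log-SD 1.0 —
the heavy-tailed shape of real FPKM distributions), with multiplicative
log-normal sample noise (SD 0.25). The ground-truth **compensation factor**
multiplies every X-linked value relative to the gene's own ancestral level,
so X:AA and X:XX share a single truth; divergence between the two ratios
can only arise from gene content, which is exactly the hypothesis the
estimators must separate.

Gene content is assigned by disjoint roles per chromosome class:
tissue-specific genes (boosted ×10 in one home tissue — emulating
secretory-tissue transcript dominance — and at 1% of baseline elsewhere;
X-linked specific genes prefer the testis-like tissue with probability
0.75), stage-trending genes (log-linear ramp over stage rank spanning e² ≈
7.4-fold; Spearman classification depends only on monotonicity, so the ramp
shape is immaterial), and unexpressed genes (all-zero rows). The
**structural-divergence scenario** fixes these fractions at the magnitudes
reported for mammalian X chromosomes: 34% tissue-specific X genes,
unexpressed fractions 0.34 (X) vs 0.20 (autosomes) — a 1.7-fold silent-gene
excess on X at the zero cutoff — versus 10%/5%/5% specific/trending
fractions on autosomes.

The outgroup inherits each focal gene's *ancestral* level: pre-compensation,
and with lineage-specific silencing undone (an unexpressed focal gene's
ortholog stays expressed), times a global species scale (default 3×) and
log-normal noise. Orthologs of focal X genes land on outgroup autosomes 1
and 4. The proteome is mRNA^b × log-normal noise (b = 1 by default; b < 1
compresses dynamic range), with zero mRNA giving zero protein. Chromatin
segmentations tile each promoter with 3 distinct states drawn per epigenome
from a fixed per-gene palette (12 states on X vs 9 on autosomes by
default), the rest of the genome quiescent; across many epigenomes the
per-gene distinct-state count recovers the palette size.

One deliberate deviation from naive uniform gene placement: TSS positions
are laid out in per-gene slots (10 kb spacing, uniform jitter within the
slot). Uniform placement would let promoters of neighbouring genes overlap,
making it impossible to emit valid non-overlapping segmentations; slotting
preserves positional randomness where it matters (within-slot) while
guaranteeing disjoint promoters.

All generators derive their streams from one seed plus fixed operation tags
(CRC32 of the tag name), so outputs are reproducible and independent of
call order; the pipeline fans one global seed out to per-stage seeds the
same way and records them in the run manifest.

What the generator does **not** emulate: read-count noise (FPKM-level
only), gene length and mappability effects, correlated co-expression
modules, cell-type mixtures within tissues, sex differences, partial escape
from X inactivation, and real chromHMM state autocorrelation along the
genome. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated statistical structure, not robustness to every
artifact of real data.

## Problem sizes and numerical choices

Recovery checks run at 2000 autosomal / 200 X genes, log-SD 1.0, averaging
20 replicate datasets per compensation factor; CI coverage uses 100
datasets with 1000 bootstrap replicates each; chromatin recovery uses 300/
100 genes over 50 epigenomes. These sizes put Monte-Carlo error well inside
the ±0.05 recovery bands while keeping the full suite around half a minute.
Degenerate inputs are errors, not silent results: empty gene classes after
filtering, all-zero τ profiles, zero Fisher margins, fewer genes than bins,
fewer than 4 samples for stage correlation. Constant expression vectors
yield missing ρ rather than an arbitrary sign. Floating-point guards
(1e-12 on rank-statistic comparisons, 1e-9 on enumeration deviations) only
absorb representation noise, never reorder genuinely distinct values.

## Limitations

The bootstrap interval quantifies autosomal-reference variability only (see
above). The tissue-specific gene definition (τ > 0.8 + max-tissue
assignment) is one reasonable convention among several; counts of
tissue-specific genes depend sharply on it. Exact Spearman p-values are
limited to n ≤ 9 samples (9! permutations); beyond that the t-approximation
is used, which is anticonservative for very small tail probabilities.
Cross-species ratios assume the 1:1 ortholog table is correct and that
median scaling is an adequate between-species normalization; systematic
expression divergence that shifts X and autosomal orthologs differently
would bias X:XX despite the AA:AA calibration.
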