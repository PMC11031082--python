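# Methods

## The haplotype function score

The unit of analysis is a 4096-bp genomic window (a *locus*). For each
individual, each of the two phased haplotype sequences at a locus is
mapped by a sequence scorer to 39 sequence-class scores — functional
genomic categories (promoter, enhancer subtypes, transcribed, polycomb,
heterochromatin, TF-binding, CTCF); a 40th, centromeric class is dropped
at the scorer boundary. The locus is assigned the sequence class with
the highest score on the reference haplotype (ties to the lowest index),
and the haplotype function score (HFS) of individual *i* is

    HFS_i = (s(h_i1) + s(h_i2)) / 2 − s(ref)

where *s* is the score in that reference class: an additive model over
the two haplotypes, centered so a homozygous-reference individual scores
exactly 0. Values are rounded to two decimals, half away from zero,
*after* centering — rounding first could move the reference off zero and
break the centering identity. The rounding deliberately zeroes
scorer-level noise: a haplotype whose class score differs from the
reference by less than 0.005 is treated as functionally reference.
Histone-mark normalization of the underlying tracks is intentionally not
applied.

### Sequence construction

Haplotype sequences are spliced from the locus's reference sequence and
the phased alleles of QC-passing variants, anchored at the locus start.
A net insertion pushes bases off the 3' end; a net deletion is padded
with N at the 3' end, so every scored sequence is exactly 4096 bp.
Variant QC per locus: imputation INFO >= 0.8 (absent passes), exact
Hardy–Weinberg p >= 1e-6 (Wigginton-style exact test, written here
because no installed package provides one), minor allele count >= 10,
genotype missing rate <= 10%; individuals missing > 10% of retained
variants are dropped from the locus. Missing genotypes that survive QC
are reference-filled (and logged); heterozygous unphased genotypes are a
hard error.

### The surrogate scorer

External deep-learning scorers plug in through a one-method contract
(4096-bp string -> finite 39-vector, deterministic). The packaged
surrogate is a motif scorer: each class owns three 6-mers with fixed
weights drawn once from a versioned manifest seed; the class score is
logistic(weighted overlapping motif count). Weights are drawn
U(0.15, 0.5) so scores sit on the responsive part of the logistic —
larger weights saturate scores near 1, where a genuine sequence edit
moves the score by less than the rounding quantum. The surrogate is
local (an edit can only change classes whose motifs overlap it),
analytic at the poly-N point (all scores 0.5), and fast; it is a testing
and simulation device, not an emulation of any trained model's biology.

## Association

Phenotypes are adjusted once: OLS residuals on covariates for
quantitative traits, logistic deviance residuals for binary ones,
followed by a rank inverse-normal transform with the Blom offset
(c = 3/8). Each locus is then tested by simple linear regression of the
prepared trait on the HFS column, with no further covariates.
Significance uses the fixed genome-wide threshold p < 5e-8; independent
hits are selected greedily, suppressing significant loci within ±200 kb
of each accepted hit's midpoint. The genomic-control factor is the
median association chi-square divided by the chi-square(1) median
(0.4549), so a calibrated test gives lambda ~= 1.

## Fine-mapping: sum of single effects

Within each LD-independent block, y = Σ_l X b_l + e with L = 10 single
effects; effect l places all its mass on one column (uniform prior
1/p) with a Normal(0, v_l) effect size. Fitting is IBSS coordinate
ascent on sufficient statistics (X'X, X'y, y'y), so cost scales with
block size, not sample size. Per effect and iteration: exact
single-effect Bayesian regression on the residual excluding that
effect; v_l maximizes the single-effect marginal likelihood by bounded
scalar optimization on log v, and is set to 0 (effect zeroed, inclusion
weights falling back to the uniform prior) unless the optimum beats the
null — the reference implementation's safeguard, with its default
threshold 0. The residual variance is updated from the expected
residual sum of squares. Convergence is declared when the maximum
absolute PIP change drops below 1e-4 (cap 200 iterations).

PIP_j = 1 − Π_l (1 − α_lj) over all L effects, matching the reference
implementation: zeroed effects contribute their uniform weights, so
loci in signal-free blocks share a common small PIP floor rather than
an exact 0. Credible sets are the smallest per-effect weight mass
reaching the coverage (0.95), reported only when the minimum absolute
within-set HFS correlation is >= 0.5 (purity; sets larger than 200 are
subsampled for the purity computation) and deduplicated. Constant HFS
columns are removed before fitting and reported with PIP 0.

Causal loci are those with PIP strictly > 0.95; loci causal for two or
more traits are flagged pleiotropic. Control loci are matched greedily
(by increasing causal p) to the nearest unused non-causal locus within
0.5 of the causal locus's log10 p, falling back (flagged) to the
globally nearest in log10 p. Enrichment of causal loci in binary
annotations uses the two-sided Fisher exact test with the sample
cross-product odds ratio (Haldane 0.5 correction, flagged, on zero
cells). Tagged variance of a locus set is the OLS R² in held-out
individuals, with a Gaussian AIC counting p + 2 parameters.

## Annotation enrichment

Per-locus baseline annotations: haplotype count, HFS range across
haplotypes scaled by |reference score| (flagged undefined when the
reference score is ~0), the 39 reference class scores, binary
genomic-region flags (overlap >= 10% of the locus, the `bedtools
intersect -f 0.1` rule with a ceiling at 410 of 4096 bp), and per-locus
aggregates of user-supplied selection statistics (max B, min allele
age, mean coalescent rate). Functional annotations are pathways (a
locus qualifies when it contains a SNP linked to a pathway gene with
link score strictly > 0.5), tissue chromatin activity and cell-type
open chromatin. Gene sets are size-filtered (> 5 and < 500 genes,
strict), ordered by average-linkage hierarchical clustering on Jaccard
distance, and adjacent sets overlapping by > 30% of the smaller lose
the smaller member; the scan repeats to a fixed point so pruning is
idempotent (a single pass is not, since removals create new
adjacencies). PIP is regressed by OLS on [baseline | one annotation] —
on its raw [0, 1] scale, by design fidelity, not a logit transform.
Significance requires a positive coefficient and Bonferroni-adjusted
p < 0.05 over the annotations tested for that trait; terms significant
in more than half of the traits are removed everywhere as probable
confounder artifacts.

## Polygenic prediction

The HFS PRS is the weighted HFS sum with SuSiE posterior effects as
weights, optionally restricted to loci above a PIP threshold. Per-block
partial scores sum exactly to the genome-wide PRS. Integration with an
external SNP-based PRS uses L1-penalized regression (optionally elastic
net) on standardized predictors, the penalty chosen by seeded 5-fold
cross-validation inside a tuning sample of at least 50 individuals;
weights are reported on the original scale. Evaluation is the squared
Pearson correlation between score and trait in held-out individuals,
and the evaluation code refuses any overlap between tuning and
evaluation ids.

## Synthetic data

`generate_synthetic_hfs` emulates a cohort's HFS matrix directly. Each
locus carries a pool of 3–10 haplotypes: frequencies are renormalized
Beta(0.2, 2) draws (a rare-skewed spectrum), the reference haplotype
(score offset 0) takes the largest frequency. Only 40% of loci draw
functional-scale score offsets (sd 0.25); the rest draw sub-quantum
noise offsets (sd 0.003) that the two-decimal rounding collapses to a
constant-zero column — reflecting that most genomic windows harbor no
common haplotype that moves their class score, which is the very reason
the method rounds. Individuals draw two haplotypes through a latent
per-chromosome Gaussian AR(1) along each block whose strength is
calibrated on a pilot draw so the realized median adjacent-locus R²
lands at the target (default 0.013, the near-independence reported for
real adjacent loci); haplotypes are ordered by score offset so latent
correlation becomes score correlation. Everything is reproducible from
one seed.

What the generator does not emulate: genuine sequence-level LD with a
heavy-tailed R² distribution (real adjacent loci are mostly independent
but occasional pairs are near-duplicates), population structure,
relatedness, and any relationship between haplotype frequency and
functional effect size. Passing tests on this generator therefore
demonstrate the statistical machinery, not robustness to the LD tail —
notably, with essentially no high-LD proxies the false-discovery rate
of PIP > 0.95 calls is near zero here, lower than on real LD structure.

`simulate_trait` draws round(1%·m) causal loci uniformly among
polymorphic columns with Normal(0, 1) effects, builds the liability on
variance-standardized causal columns (the field's standard
construction; `standardize=False` weights raw HFS instead), and adds
noise made exactly orthogonal to the liability and scaled so the
in-sample heritability equals h² exactly.

`generate_fixture_cohort` writes a self-consistent toy cohort (FASTA,
phased VCF, chromatin-state BEDs, gaps, phenotypes, truth manifest).
Active regions are planted centered on locus windows so segmentation
reproduces the windows exactly; causal loci carry an alternative
haplotype in which a 48-bp stretch is replaced by repeats of a motif of
the locus's own reference class, giving a real, rounding-robust
functional shift; planted haplotype counts are floored so every variant
deterministically clears the allele-count QC.

## Evaluation study and problem sizes

The packaged evaluation runs five replicates of: generate a 5,000 ×
5,000 HFS matrix in 50 blocks, simulate a trait (1% causal, h² = 0.1),
fit SuSiE per block, and score discrimination (AUC of PIP for causal
vs non-causal loci, ties mid-ranked) and calibration (FDR among PIP >
0.95 calls; 0 by convention when nothing is called, with the call count
reported). These sizes preserve the per-causal-locus non-centrality
n·h²/m_causal = 10 of the full-scale design (50,000 samples, ~49,000
loci, 500 causal) while remaining a few minutes of desk compute.

Two caveats of this scaling, documented rather than hidden. First, AUC
is not a pure function of per-locus non-centrality: it also depends on
block size, on the number of causal loci per block, and on the share of
monomorphic loci, none of which the scaled design preserves (100-locus
blocks with ~1 causal each versus ~450-locus blocks with ~4–5). In this
implementation the scaled design yields a median AUC near 0.85 against
the full-scale reference value of 0.92. Second, with the LD tail absent
the FDR at PIP > 0.95 is ~0 rather than ~0.06. The acceptance suite
asserts the full-scale reference values at their stated tolerances and
is expected to flag these two scale-sensitive quantities.

## Numerical choices

- Rounding: half away from zero (numpy's default rounds half to even).
- HWE exact test computed in log space via gammaln; probabilities are
  renormalized, and the tail comparison uses a 1e-12 relative guard.
- SuSiE prior-variance search over log v in [log(1e-10·var(y)),
  log(var(y))]; residual variance floored at 1e-12.
- Greedy, deterministic tie-breaks throughout: argmax ties to the
  lowest index, equal-size pathway overlap removes the later set,
  stable sorts everywhere.
- Terminal sub-4096 loci are emitted with true length and flagged; the
  scoring layer N-pads them to 4096.
- Centered loci that would cross a chromosome end are shifted fully
  inside and flagged; candidate loci overlapping an already-emitted
  locus are shifted right to abut it, or dropped if that collides with
  the next candidate.

## Known limitations

- The surrogate scorer shares only the I/O contract with trained
  sequence models; absolute scores and class assignments are arbitrary.
- PIP is modeled by OLS in enrichment regression (by design fidelity);
  coefficients near the [0, 1] boundary are not variance-stabilized.
- The LASSO integration assumes a single precomputed SNP-PRS column;
  training SNP weights is out of scope.
- Fisher's test odds ratio is the sample cross-product, not the
  conditional MLE.
- The evaluation generator's functional fraction (40%) is a realism
  judgment, not an estimate from data.
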