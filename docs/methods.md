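# Methods

## The model

The analysis treats each sequencing library as a Poisson sampling
process over transcripts. For one transcript with count *x* in a
library of *N₁* mapped fragments and *y* in a library of *N₂*, the
posterior-predictive distribution of *y* given *x* under a flat prior
on the common rate is negative binomial,

    y | x  ~  NB(r = x + 1, p = N₁ / (N₁ + N₂)),

whose mass is the classical exact-test formula
`p(y|x) = (N₂/N₁)^y (x+y)! / (x! y! (1+N₂/N₁)^{x+y+1})`. The two-sided
p-value doubles the smaller tail probability. Doubling the tail of the
distribution conditioned on *x* is not an exchangeable function of
(x, N₁) and (y, N₂) — even for N₁ = N₂, P(Y ≤ y | x) and P(X ≤ x | y)
include the diagonal term differently — so we report the more
significant of the two conditioning orientations. This makes
`ac_test(x, y, N₁, N₂) = ac_test(y, x, N₂, N₁)` hold exactly, at the
price of being marginally anti-conservative at very small counts; the
null-calibration check (below) shows the p < 0.05 rate stays at
0.051–0.053 at the depths the pipeline targets. Tails are computed via
`scipy.stats.nbinom` in one pass; the test suite checks them against
direct log-space summation of the mass function on every pair with
x + y ≤ 200 to 1e-9.

Replicates are pooled by summation within each group before testing,
because the test compares exactly two libraries. This discards
between-replicate variance; when the within-group variance/mean ratio
exceeds 2 the run logs an overdispersion warning rather than silently
trusting the Poisson model. Negative-binomial GLMs are deliberately out
of scope.

## Thresholds and tiers

Two screens are recorded side by side rather than ordered:
*significant* = fold change ≥ 2.0 (either direction) with BH FDR
≤ 0.001, and *candidate* = p < 0.05 with |log₂FC| ≥ 1.5. Both
combinations are standard in this analysis style and are not nested
(|log₂FC| ≥ 1.5 is ≈ 2.83-fold); keeping both as tiers lets a caller
choose either convention. Fold changes are computed from group-mean
FPKM with a 0.01-FPKM pseudocount that never enters the exact test —
it only prevents infinite ratios on zeros.

FPKM uses exonic length, not genomic span. A prefilter (default FPKM
≥ 0.1 in at least half the samples) runs before correlation only,
because rank correlations on all-zero vectors are undefined; it is
configurable to off and is logged.

## Pairing

Correlations are computed across all samples of the two compared
groups jointly, on raw FPKM (a `log1p` switch exists). The joint axis
is what lets condition-driven covariation register: two transcripts
that both respond to the mutation correlate strongly across the pooled
samples, which is precisely the signal the TAR-pair logic exploits.
Spearman is Pearson on mean-fractional ranks; the vectorised
implementation is tested for equality against a scipy per-pair loop.

The cis window extends 10 kb upstream of the transcription start and
20 kb downstream of the transcription end of the **mRNA**, oriented by
the mRNA's strand (for a minus-strand mRNA "upstream" is the
higher-coordinate side); the lncRNA's own strand is ignored, the
boundary is inclusive, and gene-body overlap counts as cis. Pairs
outside the window need a hybridization energy at or below
−30 kcal/mol (configurable; energy tables are ingested, never
computed — thermodynamic prediction is out of scope). Pairs that are
neither are rejected rather than guessed.

The TAR-pair cascade filters on `min_abs_fold`, the smaller of the two
members' fold magnitudes after inverting folds below 1, so
"≥ 5-fold increase **or** decrease" is a single rule; by construction
`refine(build(·, 2), 5) ≡ build(·, 5)`, an identity the tests assert on
random inputs.

## Coding potential

CPC < 0, CNCI < 0, txCdsPredict < 500 (all strict) vote noncoding; a
pfam domain hit votes coding, counted as a full fourth vote. A label
requires three agreeing votes; 2–2 ties and transcripts with too few
votes stay `unclassified` and never enter the lncRNA set. The internal
surrogate scorer (ORF fraction, 2× ORF length, and an in-frame hexamer
log-odds score built from human codon-usage frequencies against a
mononucleotide background) exists so the pipeline can run
self-contained; it mimics the threshold semantics of the external
tools, not their algorithms, and never asserts a pfam hit.

## qPCR and enrichment

ΔCt normalizes each target Ct to the arithmetic mean of the
housekeeping-gene Cts within the same sample (equivalent to a
geometric mean of linear abundances; how discordant references should
be reconciled is a package decision, not a given). ΔΔCt subtracts the
control-group mean ΔCt, fold = 2^−ΔΔCt, and groups are compared by a
two-sided equal-variance t-test on replicate ΔCt values (Welch
optional). Normalization makes the result exactly invariant to adding
any constant to all Cts of one sample, which the tests check to 1e-10.
Amplification-efficiency correction is out of scope.

Over-representation is the one-sided hypergeometric tail P(X ≥ k) with
BH across sets; term databases are user-supplied GMT files.

## The synthetic-data generator

The generator emulates the *statistical* structure of a two-condition
iPSC transcriptome comparison, not its biology. Defaults: 60 mRNAs and
40 lncRNAs, 6 replicates per group, baseline mean 200 fragments per
transcript, 20 DE mRNAs and 16 DE lncRNAs at |log₂FC| 2.5 (≈ 5.7-fold,
chosen to sit past the 5-fold cascade the way validated pairs did),
8 cis and 4 trans planted pairs with latent co-expression 0.95, Poisson
noise (gamma-Poisson available as a stress mode). Replicate counts per
condition are a testability choice; the sequenced study pooled
libraries per condition and does not fix them.

Geometry is deterministic: mRNAs occupy 200-kb slots on chr1
(alternating strand), cis partners are placed 3–4 kb beyond the
partner's downstream end (inside the window on either strand), trans
partners live on chr2 with planted energies of −50…−35 kcal/mol, all
remaining lncRNAs on chr3. The spacing guarantees planted cis pairs
satisfy the window and nothing else can, which is what makes the
recovery test's false-discovery count meaningful. Decoy energy rows
(−10…−2 kcal/mol, below any plausible cutoff) exercise the threshold
without creating true trans pairs.

Co-expression uses a shared log-normal latent factor: each member's
log-factor is `σ(√ρ·Z_shared + √(1−ρ)·Z_own)` with σ = 0.5, mean-one
correction applied, multiplying the Poisson mean. The transform is
monotone, so both Pearson and Spearman respond, and the latent
correlation is exactly ρ.

Simulated library sizes are the in-matrix column sums plus a constant
2×10⁶ fragments representing reads mapped outside the quantified
subset, as real totals do. Without this, planting strong DE in a
100-transcript matrix shifts the column sums themselves and biases
every FPKM fold estimate compositionally — an artifact of tiny
matrices, not of the method. The totals are written to a
`library_sizes.tsv` sidecar that the pipeline ingests.

What the generator does **not** emulate: batch effects, isoform
structure, length-dependent sampling, GC bias, or correlated nulls.
Passing recovery tests therefore demonstrate that the implementation
recovers the structure it defines — they are correctness checks of the
statistics, not evidence about real FUS-mutant data.

## Problem sizes and numerical choices

The recovery check runs the full pipeline on 20 seeds of the default
configuration (100 transcripts × 12 samples each, ~1 s total); null
calibration uses 10,000 transcripts at 6+6 replicates; oracle checks
cover every count pair with x + y ≤ 200, a 50×50 pairing instance, all
lncRNA placements on a 200-kb toy chromosome at 101-bp steps, and
hypergeometric universes up to N = 60. All randomness flows through
explicit seeds; analysis stages are fully deterministic, and
`summary.json` (sorted keys, no timestamps) is byte-identical across
reruns. Ties in Spearman ranks use mean ranks; constant expression
vectors are excluded before correlation with a logged warning rather
than propagating NaNs.

## Known limitations

* The pooled exact test understates uncertainty under real biological
  overdispersion; the warning is a flag, not a correction.
* Gene-level analysis is available only as transcript-count summation;
  no isoform deconvolution.
* The cis window convention (mRNA-anchored, span-to-window
  intersection, inclusive bounds) is one defensible reading of
  "10 kB upstream or 20 kB downstream"; the window extents are
  configurable because the convention is not uniquely determined.
* The trans energy cutoff (−30 kcal/mol) has no published reference
  value and is logged prominently on every run.
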