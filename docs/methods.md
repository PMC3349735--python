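# Methods

This note documents the models, procedures and numerical choices behind
`tfbindmode`, and what the synthetic-data tests do and do not establish.

## Coordinates and peak confidence

All intervals are 0-based half-open; the narrowPeak summit field is a 0-based
offset from the region start. The high-confidence peak set consists of
replicate-2 regions — retaining their own coordinates, not the intersection
interval — that overlap (≥ 1 bp, configurable) at least one replicate-1
region; replicate-2-only regions form the low-confidence set. The FDR filter
(strictly below 10%, stored as percent in MACS convention) is applied to each
replicate before intersection. Nearest-gene assignment minimises
|summit − TSS| on the same chromosome; ties go to the smaller TSS coordinate,
deterministically. The signed distance is negative when the summit lies 5′ of
the TSS in the gene's orientation. Genomic-distribution categories use the
precedence promoter (≤ 10 kb upstream of a TSS) > gene body > downstream
(≤ 10 kb past the TTS) > intergenic, against a seeded uniform-summit baseline.

The region-overlap permutation test keeps set A fixed and re-places each set-B
region uniformly within its own chromosome, preserving lengths and
per-chromosome counts; the statistic is the number of A regions overlapped,
with one-sided empirical p = (1 + #{perm ≥ obs})/(n_perm + 1) and a z-score
from the permutation mean/sd. Default n_perm = 1000.

## Word-based motif counting

Motif search is exact IUPAC-word matching, not PWM scoring — the analysis
counts exact consensus matches, for which a weight matrix adds nothing. Both
strands are scanned by matching the reverse complement of the pattern on the
forward sequence; footprints are always reported in forward coordinates, and
a footprint matching on both strands (every hit of a palindromic pattern such
as `TGANTCA`) is collapsed to a single `+` hit so palindromes are not double
counted. An `N` in the sequence matches only a pattern `N`.

Octamer-family site counting collects all hits of the octamer's three hexamer
derivatives on both strands, collapses identical footprints, and selects
greedily left-to-right by footprint start, skipping any hit that overlaps an
already selected footprint on either strand (a site is a genomic footprint,
not a strand-specific event). Greedy-by-start selection is optimal for
equal-length intervals; the test suite verifies this against an exhaustive
maximum-independent-set search. The "inverted" background motif is the
reversed word (`TGAAGGCC` for `CCGGAAGT`) — the reverse complement would be
redundant with both-strand scanning, so reversal is the only inversion that
yields a distinct background.

Composite ETS–SRF modules pair any ETS hit (union of the strong and variant
hexamer derivatives by default) with any SRF CArG hit (`CCWWWWWWGG`) such
that both motif centres are within 100 bp (inclusive) of the peak summit and
the centre-to-centre distance is strictly below 50 bp. Distances are measured
centre-to-centre; this choice, and both thresholds, are configurable.

## Expression model

The design crosses siRNA treatment (control vs focal-factor knockdown) with
stimulus (0 vs 30 min), three replicate batches pairing samples across all
four conditions. Signals are log10 scale.

Probeset collapsing applies three rules in order: (1) probesets at or below
the background level — default: the 2.5th percentile of all signals, since no
external definition of array background is available — in the stimulated
control samples are discarded; (2) genes whose significantly changed
probesets (pooled knockdown contrast, p < 0.05) disagree in direction are
excluded; (3) only the probeset with the largest absolute knockdown effect is
retained per gene (ties broken by probeset id).

Differential response per contrast (knockdown effect at 0 min, at 30 min, and
the stimulus effect) uses the two-factor additive model with batch pairing,
fitted per gene on the cell/batch means: the residual mean square, with
(4 − 1)(B − 1) = 6 degrees of freedom for B = 3 batches, is the shared error
term for every contrast t-test. This is a transparent stand-in for a
moderated-t pipeline: it is the same linear model, without empirical-Bayes
variance shrinkage, and the substitution is recorded in the report metadata.
At the generator's default effect/noise ratio (0.3 log10 units, σ = 0.1) its
per-contrast power has the closed noncentral-t form and equals 0.862; the
power test checks the empirical rate against that prediction rather than an
aspirational constant, because no exact paired test at these settings can
exceed it. Multiple testing uses Benjamini–Hochberg as the q-value stand-in;
regulated genes require p < 0.05 and q < 0.1, both thresholds configurable.

Per-gene response profiles are the four condition means z-scored with the
sample (n−1) standard deviation — condition means, not replicate values, are
standardised; flat profiles are excluded. k-means uses k = 8 with k-means++
initialisation, 20 restarts, and a fixed seed; scikit-learn's implementation
never returns an empty cluster. Display order 1..8 comes from average-linkage
hierarchical clustering of the cluster means. Cluster↔binding-mode
association tests each cluster's 2×2 (membership × mode) by chi-square,
switching to Fisher's exact test whenever an expected cell is below 5; the
same switch governs all 2×2 tests in the package.

## Association statistics

The default chi-square carries no continuity correction — on the published
FOS-by-regulation table (27/141 vs 13/137) the uncorrected test reproduces
the printed p = 0.021 (0.0218), while the Yates-corrected value (0.034) does
not. The gene-list overlap z-score samples 10,000 background lists uniformly
without replacement (the sampling scheme is otherwise unspecified; without
replacement matches list semantics) of the size of the second list and reports
(observed − mean)/sd; its background moments converge to the hypergeometric
closed form, which the tests check at three Monte-Carlo standard errors.
Hypergeometric gene-set enrichment reports the raw upper-tail p per term,
−log10 p, and a BH-adjusted column; the raw p is conservative on the discrete
lattice, so the null-calibration test asserts stochastic dominance over the
uniform rather than distributional equality. Per-category cluster enrichment
follows the ratio>1 partition rule (clusters "crossing the line" vs the
rest); note this partition is selected by the data, so its p-value is exact
only under the idealised uniform null.

## Synthetic data generator

The generator's defaults encode the study conditions the pipeline is meant to
face: 303 unique and 226 redundant regions of 400 bp; 26% / 93% of summits
within 2 kb of a TSS; comparator peaks covering the interior of every
redundant region and no unique region (making the classes separable by
construction, so classification can be tested for exact recovery); strong-site
count distributions peaking at 3 per redundant and 1 per unique region, with
30% of unique regions carrying only the variant word; SRF CArG rates of
54% / 27%; composite-module rates of 25% / 4% (modules are drawn as a subset
of SRF-positive regions so both marginal rates stay at their configured
values); AP1 rates 40% / 10%. Replicate 2 is replicate 1 jittered by
N(0, 20 bp); 10% of regions appear only in replicate 2; 5% of FDR values
exceed the 10% cut-off. Standalone CArG words are planted > 100 bp from the
summit (even under jitter) so that only module-flagged regions satisfy the
module rule by construction.

Genes are tiled at fixed spacing (~10 kb at the defaults) so proximal and
distal placement are always possible, with one hosted region per gene.
Expression archetypes are eight well-separated response shapes over the four
conditions; genes bound by unique-class regions draw archetypes with 7:1 odds
on the two knockdown-down shapes (2 and 4), redundant-class genes on the two
knockdown-up shapes (7 and 8); unbound genes are flat. Signals are gene
baseline (uniform 1.5–3.5) + probe offset (σ = 0.1) + 0.3 × centred archetype
+ N(0, 0.1) per replicate — about 25% CV noise and two-fold effects, typical
of expression arrays. Multi-probeset genes, dead below-background probesets
(5%) and opposite-direction probeset pairs (2%) exercise every collapsing
rule. Gene-set categories couple to binding mode (cytoskeleton/migration to
unique, gene-expression machinery to redundant, survival mixed) plus uniform
decoys.

Background sequence is i.i.d. uniform and spurious word occurrences are *not*
suppressed: a 400 bp region has ≈ 0.6 expected spurious strong-family hexamer
hits and a ≈ 2.4% chance of a spurious CArG. Tests that need exact counts
rebuild region sequences from the planted-site ledger over a neutral
background; statistical recovery tests either include the closed-form
spurious correction or rely on the planted distributions being peaked enough
for the modes to survive.

What passing these tests shows: every algorithmic rule behaves as specified,
planted parameters are recovered at the documented precision, and the full
chain is deterministic per seed. What they do not show: robustness to real
ChIP artefacts (mappability, GC bias, copy number), to correlated probe
effects or array batch pathologies, or to motif statistics of non-uniform
genomic background — none of which the generator emulates.

## Determinism and problem sizes

A single global seed fans out to per-stage streams via blake2s hashing of
stage names, so any stage is reproducible in isolation; identical
configuration and seed give byte-identical bundles and reports. The default
end-to-end run uses a 4 × 2 Mb genome, 800 genes, ~530 regions, ~1,100
probesets, 1,000 permutations for the region-overlap test and 10,000
background lists for the overlap z-score, and completes in a few seconds on
one CPU; these sizes were chosen so the full statistical structure is present
while the whole analysis stays interactive.
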