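# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test suite, and the numerical choices the package
makes where the underlying method leaves room.

## Divergence testing by composition-matched resampling

For an ortholog pair with mappable lengths L_B, L_Y (total CDS length
by default; an optional mappability mask can subtract ambiguous bases)
and marginal nucleotide frequencies π_B, π_Y computed over the CDS, the
null distribution of the log2 expression ratio is built by bootstrap
from a single *source* gene's base-level 5'-end counts.  One pseudo
total per target gene is formed by drawing, with replacement, n_b
positions carrying base b from the source, where {n_b} partitions the
target's length L across the four bases in proportion to the target's π
(largest-remainder rounding, ties broken by base order A,T,G,C).  Base
classes absent from the source have their quota reallocated
proportionally among the present classes.  The null statistic is
log2((pseudo_Y + 0.5)/(pseudo_B + 0.5)); because the two pseudo totals
already carry the two lengths and compositions, no further length
normalization is applied, and the null centres where the observed
statistic centres under equal per-base rates.

Each of the four components — source strain ∈ {B, Y} × replicate ∈
{1, 2} — yields a two-sided empirical P value

    P = min(1, 2 · min(#{null ≤ obs} + 1, #{null ≥ obs} + 1) / (N + 1))

against the observed per-replicate ratio; the maximum of the four is
retained (a gene must beat every null to be called) and BH-adjusted
across genes at FDR ≤ 0.05.  The (+1)/(N+1) estimator keeps P strictly
positive; ties count on both sides, so the estimator is exactly
symmetric under a strain-label swap.  The resampling streams are keyed
by (seed, assay, replicate, source gene, target gene), which makes a
label swap negate every observed ratio and every null draw while
leaving all P values bit-identical — a property the tests assert
exactly, not approximately.

Counts are scaled to the assay's mean library size before ratios (the
pseudocount is applied after scaling).  Cross-library ratios are not
meaningful without some normalization; total CDS-assigned reads per
library is the denominator.  A `normalize=False` switch exists because
a global normalizer absorbs, by construction, any shift shared by all
genes: cohorts in which *every* gene carries the same planted fold
change (used for power measurement) are evaluated unnormalized, which
is valid because the simulator generates depth-matched libraries.

### Translation efficiency

TE divergence tests the null that log2[RFP(B/Y)] equals
log2[mRNA(B/Y)].  Nulls are resampled from each strain's *own*
footprint counts (pseudo_B from B's RFP with L_B, π_B; pseudo_Y from
Y's RFP with L_Y, π_Y), producing a null RFP ratio centred on the
observed one, against which the observed mRNA ratio is compared; the
reciprocal comparison resamples the mRNA counts against the observed
RFP ratio.  With two replicates this gives four P values.  The maximum
is retained only if the per-replicate TE difference
d_r = log2[RFP(B/Y)]_r − log2[mRNA(B/Y)]_r has the same sign in every
replicate; otherwise the gene is non-significant (P = 1).  Because the
null carries only one assay's sampling noise while the observed
difference carries both, the raw component P values are mildly
anti-conservative; the max-P rule and the direction-agreement
requirement are what restore specificity, and the test suite verifies
on simulated true-null cohorts (equal shifts in both assays) that the
false-call fraction stays within calibration error.

Genes are retained in an assay when each strain's pooled replicates
carry at least 50 CDS-assigned reads (per-strain pooled totals; a
stricter per-library variant can be had by pre-filtering libraries).
Regulatory categories combine the mRNA and TE significance flags at
FDR ≤ 5%: mRNA-only, TE-only, both, neither.

## Ribosome residence time

Footprints of length ≥ 27 nt whose 5' end falls on a codon boundary
are kept; longer reads are truncated to their 5'-most nine codons for
positioning, so every retained footprint spans nine codons and the
central codon of a 17-codon window can appear at nine footprint
positions (position p means the central codon is the p-th codon of the
footprint; A-, P- and E-sites are positions 6, 5, 4).  For each sense
codon, every window in which the codon occurs uniquely at the middle
contributes its count vector over the nine positions; windows with
zero footprints are excluded (their RF is undefined), and the reported
window count is the number of contributing windows.  Per-window RFs are
averaged across windows and divided by the uniform expectation 1/9
(11% when rounded) to give RRT.

Significance comes from permuting the nine position labels of each
window's count vector independently (not from a pooled shuffle),
recomputing the mean RF per permutation, and applying the two-sided
empirical estimator above.  The stalling filter requires
max(RRT, 1/RRT) ≥ 1.2, P ≤ 1e-4 and ≥ 300 windows; the symmetric
effect criterion treats under-represented occupancy (RRT < 1) on the
same footing as dwell, since RRT is a positive ratio and a literal
absolute value would be vacuous.  Note an arithmetic consequence of the
unbiased P estimator: its smallest attainable value is 2/(N+1), so
N = 10,000 permutations cannot reach the 1e-4 threshold; the package
defaults to 10,000 for exploratory tables but the test suite and any
run intended to apply the 1e-4 filter use N = 19,999, for which the
minimum P is exactly 1e-4.

The between-strain comparison permutes both strains' windows jointly
and compares the observed ratio of mean RFs (equal to the RRT ratio)
with the permuted ratios, using the same effect/P/window criteria with
the window requirement applied to both strains.  Permutation streams
are keyed by window content rather than strain label, so a label swap
inverts every ratio with identical P values.

Under the placement model, a planted dwell multiplier m at one position
yields an expected RRT of 9m/(m + 8) rather than m (the window's other
eight positions share the remaining mass): m = 1.5 gives ≈ 1.42, which
is what the estimator recovers on simulated data.

## Annotation refinement and ORF variants

Predictions are classified against the existing annotation by genomic
span overlap: none → new; exactly one, same strand → extended /
trimmed / unchanged by length; two or more, or conflicting → ambiguous
and never refined.  Evidence rules: new models need ≥ 50 mRNA and ≥ 50
RFP reads on the predicted CDS and ≥ 150 nt (the printed "150 bp (50
amino acids)" is internally inconsistent — 150 bp is 50 codons
including none for the stop — and is implemented as CDS ≥ 150 nt,
configurable); extensions need ≥ 20 reads of each assay on the added
region plus their own start and stop codons; trims are kept only with
zero reads of either assay on the removed region.  Reads are counted by
the position of the 5'-most nucleotide, matching the feature-assignment
rule, and pooled across replicates.  Accepted models always begin with
ATG and end on a stop codon in their own frame.

5'-extension candidates are the 5'-most in-frame ATG within 180 bp (60
codons) upstream of the annotated start with no in-frame stop between
it and the start; 3'-read-through regions run from the annotated stop
(exclusive) to the first in-frame stop within 180 bp downstream
(inclusive), with an immediately following stop (zero added codons)
reported as no candidate.  Candidates are purely sequence-determined.
Confirmation needs ≥ 10 reads in both assays with 5' ends in the region
and ≥ 80% of region bases covered by full aligned spans in both assays
— span coverage, because 5'-end-only occupancy could never reach 80% at
ten reads.

## Read mapping and feature assignment

Footprint libraries carry up to three spurious 3' adenines, so mapping
is iterative: the 3'-most base is removed one at a time until the read
aligns, down to 23 nt, with at most two mismatches.  At the first
mappable length the unique minimum-mismatch placement is reported;
ties, including equal-quality placements at two loci, make the read
unmapped.  The built-in aligner is a seed-free exact scan meant for toy
genomes (≤ ~1 Mb); real data should be aligned externally and ingested
as SAM/TSV, to which only trimming bookkeeping and assignment apply.

Feature assignment uses the 5'-most nucleotide alone, against
transcript-oriented half-open windows: CDS = [start − 16, end − 14),
5'UTR ends at start − 16 (so a 5' end exactly 17 nt upstream is UTR, 16
nt upstream is CDS), introns lose their last 8 nt, and the 3'UTR runs
from end − 13 to transcript end − 28.  All eight offsets are
configuration values; the defaults encode the most self-consistent
reading of the assignment convention, validated against overlap at
configuration time.  CDS-assigned reads whose 5' end falls in the short
upstream margin are clamped to the first CDS base so that coverage sums
equal CDS read counts exactly.

## The synthetic-data generator

The generator emulates the two-strain design at desk scale.  Strain B
coding sequences are random stop-free codon strings at a configurable
GC content (default 0.38, yeast-like); strain Y is a point-substituted
copy (default rate 0.02, no indels, so ortholog coordinates coincide),
with start/stop codons and planted variant contexts protected and
substitutions never creating an in-frame CDS stop.  Genes sit in
blocks — 60 nt pad, 180 nt upstream context, CDS, 180 nt downstream
context — on random strands of a single chromosome.  Planted 5'
extensions write a stop codon, an ATG and stop-free/ATG-free codons
into the upstream frame; read-throughs write stop-free codons and a new
stop downstream.

Base-level counts are negative binomial with per-base mean
depth/length (default 500 reads per gene and library, two replicates)
and variance μ + μ²/k (default dispersion k = 2; k = ∞ gives Poisson),
multiplied by log-normal positional rate multipliers (σ = 0.3, unit
mean) shared between strains and replicates to mimic sequence-driven
coverage bias.  Planted log2 fold changes split symmetrically between
the strains (B × 2^(−l/2), Y × 2^(+l/2)).  Because the multipliers are
shared, the bootstrap null — which sees them as position-to-position
variance — is slightly wider than the sampling distribution of the
observed ratio, making the divergence test mildly conservative; the
measured type-I rates in the test suite reflect this.

Footprints are placed pre-aligned on codon boundaries with probability
proportional to the product of dwell multipliers of the codons covered
at their specified positions (uniform with an empty dwell map), and can
be rendered as raw reads carrying 0–3 spurious 3' adenines to exercise
the trimmer.  All randomness flows from one root seed through named
substreams (genome, coverage, footprints).

What the generator does *not* emulate: gene-level expression
variability across genes (all genes share the configured depth), rRNA
contamination, UTR transcription, introns, indel divergence between
strains, and library-prep biases beyond the 3' adenines.  Passing tests
therefore demonstrate correctness of the procedures and their
calibration under a faithful but simplified sampling model, not
performance on the full complexity of real libraries.

## Problem sizes and runtime choices

The validation suite uses desk-scale cohorts chosen to keep statistical
resolution meaningful: 2,000 null pairs at depth 500 with 1,000
resamples for type-I calibration; 200-pair cohorts for power and TE
specificity; 120 genes of 1.2–1.8 kb (≥ 300 windows for each proline
codon) with 100,000 footprints and 19,999 permutations for dwell
recovery.  Resampling is vectorized per gene (all N pseudo totals of a
component drawn in one pass) and permutation nulls are generated by
chunked in-place row permutation, so the full suite runs on one CPU in
minutes.
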