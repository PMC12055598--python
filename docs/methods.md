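# Methods

## Scope and input model

`leukopore` consumes aligned nanopore reads (BAM/SAM; primary +
supplementary records merged per molecule) with per-read channel and
timing metadata, a genome model (chromosome lengths, centromeres, arms), a
target panel and a repeat mask, and produces a digital karyotype, fusion
calls, focal CNV calls, targeted small-variant calls and detection-latency
statistics. Basecalling and alignment are upstream concerns; the simulator
emits alignments directly from truth so the test suite needs neither.

All internal coordinates are 0-based half-open; conversion to 1-based
happens only when writing VCF.

## Digital karyotype

### Estimator

Reads are counted, not bases: each molecule contributes one count to the
bin containing the reference midpoint of its *longest* alignment segment
(split fusion reads therefore count once). Adaptive sampling shortens
off-target molecules but does not change how many molecules are sampled
per locus, so reads-per-bin is flat across on/off-target regions while
base coverage is enriched — this invariance is asserted in the test suite.

Bins overlapping the centromere or mask, or truncated by the chromosome
end, are excluded. Depth levels are summarized per arm with an
interpolated (grouped) median: bin counts are small integers, and the
plain median's 0.5-quantization is large enough relative to the level
spacing to mislead model selection, while the grouped correction keeps the
median's robustness to outlier bins.

### Mixture model and fit

For a specimen with blast fraction `f`, per-haploid-copy depth `μ`, and
blast-clone copy number `n_c`, the expected level of chromosome (arm) `c`
is `μ·(N_c(1−f) + f·n_c)` with `N_c` the normal-cell copies. Arm levels
are clustered into discrete depth levels (two values join one level unless
separated by both 4 combined standard errors and 5% of the level). The
lattice is then fitted over a grid of `f ∈ {0.05, …, 1.00}` (step 0.01),
an XX/XY hypothesis, and μ anchors derived from assigning the
heaviest level 1–4 copies; given an assignment, μ is re-estimated in
closed form (three rounds). X and Y are fitted jointly as their own
observations: in a male sample they pin the haploid depth level, which is
decisive below.

### Degeneracy and model selection

A profile with only two or three distinct depth levels is consistent with
many integer lattices (a near-haploid {1,2} profile is exactly reproduced
by a doubled {2,4} reading — the masked-hypodiploidy ambiguity known from
clinical genomics — and by more exotic lattices such as {2,5}).
Candidates whose extra misfit lies within the sampling noise of the level
estimates (best objective + 3× the analytic noise floor `Σ 1.56·m`) are
therefore ranked structurally, in order:

1. candidates whose sex hypothesis contradicts the observed Y depth are
   dispreferred (an XX reading of a male profile can abuse Y's zero
   baseline to fit any level);
2. uniform autosome assignments are only acceptable at n = 2 (balanced
   whole-genome scaling reads as diploid);
3. occupied copy numbers must sit ≤ 2 apart (lattices like {2,7} are
   reparameterization artifacts, not karyotypes);
4. irreducible assignments (gcd of autosome copies = 1) beat their
   doubled/tripled equivalents;
5. most autosomes at n = 2; 6. total count closest to 46;
7. objective; 8. largest blast fraction (an unidentifiable euploid
   profile then reads as a pure diploid tumor, which keeps the downstream
   copy-number formulas well behaved).

Arm-level events are reported only when the two arms' fitted integers
differ *and* the arms' bin-count distributions diverge by the KS criterion
below; the arm closer to the genome-wide modal copy number is what the
chromosome contributes to the total count, so a `+11q` gain does not
inflate a 38-chromosome hypodiploid count.

Known limitations: balanced whole-genome doubling is reported as diploid;
a whole-chromosome tetrasomy that is the *only* lesion in a female
pure-tumor profile can be reported as its halved equivalent (no odd-copy
chromosome anchors the lattice); calls below 30% fitted blast fraction
are flagged low-confidence rather than trusted.

## Kolmogorov–Smirnov divergence and detection latency

Two chromosomes (or arms) diverge when the two-sample KS test on their
usable bin counts gives p < 1e-9 (asymptotic, the appropriate regime for
hundreds of bins) *and* the relative median difference — measured against
the mean of the two medians, a symmetric and scale-free denominator —
reaches 20%. The test suite checks the D statistic against brute-force
ECDF enumeration for n ≤ 8 and validates an exact permutation p-value
oracle against the exact small-sample distribution.

Earliest karyotype detection replays the run on a one-minute grid of
cumulative reads (a read contributes once *finished* — data exist only
after the molecule completes). Detection requires the fitted count to
cross ≥ 53 (or ≤ 39) chromosomes and every chromosome fitted away from
the modal copy number to pass the KS criterion against at least one
modal-copy chromosome. Fusion detection times are not grid-snapped: they
are the finish time of the second independent (post-duplex-collapse)
supporting read plus a conservative 300-s analysis latency.

## Fusion calling

Segments overlapping the mask are discarded before anchoring. An anchor
requires ≥ 500 *aligned query bases* (CIGAR M/=/X — the robust reading for
indel-rich nanopore alignments, rather than reference span) within 5 kbp
of a panel gene. Duplex collapsing groups reads by anchored gene set and
channel and merges transitive chains of start times within 30 s, keeping
the earliest; reads without metadata pass through as independent —
static results must not silently change with metadata availability.
Junction coordinates (the segment ends adjacent to the split in read
coordinates) are clustered with a 50-bp tolerance, accommodating the small
indels real double-strand-break repair leaves at breakpoints while
separating distinct events. Orientation is annotated compatible when the
molecule traverses both genes with (or both against) their coding
direction. No positional deduplication is applied: native DNA has no PCR
duplicates.

## Focal CNV

Per-nucleotide depth (base-level, CIGAR-aware: deletions and split-read
gaps contribute nothing) is meaningful within enriched regions, where
reads are full length. Deletion candidates come from split reads (same
chromosome and strand, reference gap ≥ 50 bp, query gap ≤ 30 nt, clustered
at 50 bp) and from depth runs below the halfway level to one copy less.
The carrier fraction solves the mixture

    depth_in / depth_flank = (2(1−f) + f(n_c − cf·Δ)) / (2(1−f) + f·n_c)

for the smallest integer Δ ≥ 1 with cf ≤ 1. At ≥ 10× flanking depth a call
needs split support ≥ 2 *or* a near-clonal integer drop (cf ≥ 0.8); below
10× both evidence types are required and the call is flagged
low-confidence. Region copies are `round((2·d_rel − 2(1−f))/f)` against a
diploid baseline taken from panel regions on chromosomes fitted at n = 2
(adaptive sampling makes off-target base depth non-comparable). iAMP21
requires ≥ 4 RUNX1 copies inside an amplification interval that is focal:
shorter than the 21q arm with flanking depth below the region — the
quantitative reading of "focal" is a documented package choice, echoed in
the call's rationale string.

## Targeted small variants

Calling is restricted to enriched regions (uneven adaptive-sampling
coverage defeats genome-wide nanopore SNV callers) and proceeds in two
passes. Pass 1 builds a pileup consensus from the existing alignments:
substitution columns keep the *majority* base — inserting a 0.4-fraction
allele would misalign the 0.6 majority in pass 2 — while insertions and
deletions supported by ≥ 0.3 of junction-spanning reads are incorporated
(this is what makes a 50%-fraction FLT3-ITD reliably present in the
consensus). Insertion content is polished by medoid selection plus
column voting over the supporting reads' inserted sequences. Pass 2
realigns every overlapping read to the consensus (edlib edit-distance
alignment; a unit-cost aligner may scatter a long indel across a tandem
repeat, so deletion evidence is counted in a padded window) and
re-measures allele fractions; variants vs the original reference at ≥ 0.3
with ≥ 10 covering reads are reported. "MAF" is read as alternate-allele
fraction so homozygous variants (fraction 1.0) are reportable. Two
variants share a phase group when ≥ 90% of ≥ 5 co-covering reads carry
both-or-neither alternate.

ITD classification aligns the consensus globally to the reference, merges
insertion runs within 60 bp, re-extracts each merged event exactly by a
local common-prefix/suffix diff, and requires ≥ 9 inserted nt matching the
immediately adjacent reference segment at ≥ 80% identity. In silico PCR
scans each read (both orientations) for the forward primer and the
reverse-complemented reverse primer at ≤ 3 edits; the amplicon is the
inclusive span between outer primer ends; reads gaining ≥ 9 nt over the
reference span count as ITD, reads within ±9 nt as wild type, and the
allelic ratio is ITD/WT (flagged infinite rather than numeric when no
wild-type amplicons exist).

## Simulator

The simulator is first-class, tested code: it draws molecules arm-by-arm
with density `N(1−f) + f·n` (the exact signal the karyotype reads out),
assigns channels, start times, and durations at 400 nt/s, truncates
off-target molecules to 600–700 nt under the adaptive-sampling model,
emits split alignments for fusion and deletion molecules, and appends
complementary-strand duplex twins on the same channel within the duplex
window. Sequence-level reads for targeted regions are generated from
explicit haplotype edit scripts; CIGARs are composed from the known edits
plus a per-base error process (defaults 1% substitution, 0.5% insertion,
0.5% deletion; the ITD scenarios use 3/1/1% for ~5% total), which
left-anchors indels consistently the way real aligners do. Identical
seeds give byte-identical BAM and truth JSON.

Default desk-scale conditions: a 1/100-scale 24-chromosome genome with
GRCh38-proportional lengths and centromeres, 10-kbp bins, 120,000 reads
per karyotype scenario (≈ 35 reads/bin — comfortably above the ~30/bin
where integer recovery saturates, and enough power for the arm-level KS
confirmation in the +11q scenario), log-normal read lengths (median
8 kb), and ~40× regional depth for consensus calling. What the simulator
does *not* model: signal-space artifacts, chemistry-specific error
profiles, GC/mappability coverage waves, multi-clone architectures, or
reference repeat structure (the random reference has no segmental
duplications, so the mask machinery is exercised by construction rather
than by realistic ambiguity). Passing tests demonstrate the estimators
invert the stated generative model at realistic noise levels, not
performance on any particular patient cohort.

## Numerical and interface choices

- Channel/time metadata tag names (`ch`/`st`/`du`) are configurable;
  ONT-style `key=value` fallbacks are parsed from read names/CO tags.
  Reads lacking metadata join all static analyses but never duplex
  collapsing (conservatively independent) or timing.
- Degenerate inputs fail loudly: all-zero depth, missing diploid
  baseline, sub-threshold region depth, malformed BED lines (reported
  with line numbers), invalid configuration values.
- Ties: junction clusters are built in sorted order; report field order
  is deterministic; every stochastic routine takes an explicit seed.
- The CLI is a thin veneer: exit 2 for usage errors, 1 for analysis
  errors; `classify` output is the union of the per-module subcommands.
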