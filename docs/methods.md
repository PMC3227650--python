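# Methods

## Scope and model overview

`pyrofrag` models a pooled 454-style (GS Junior class) sequencing run of an
equimolar mixture of long-range-PCR amplicons, prepared with one of three
fragmentation methods — nebulization, sonication, or enzymatic digestion —
in three replicate libraries each, and then computes the statistics used to
compare the methods. All raw data are synthetic; the only empirical inputs
are a bundled nine-replicate validation table (seven Sanger-validated
positions with per-replicate coverages and major-allele percentages) used
as ground truth for the replicate-pooling arithmetic.

## Simulation model (simdata)

**Reference and panel.** The default reference is a fixed 49,000 bp random
ACGT sequence (its own seed is constant, so the "genome" does not change
with the run seed), labelled chr1 starting at position 99,725,000 (1-based).
Eight overlapping amplicons tile it: five of 8.4–9 kbp and, in an interior
window, three short ones of 2.5, 2.0 and 1.2 kbp, with 60 bp overlaps. The
exact geometry is stylized: with eight amplicons of at most 9 kbp the
published layout cannot be reproduced literally, and none of the computed
statistics depend on it. Coordinates are 0-based half-open internally and
1-based closed in reports.

**Fragmentation.** Each molecule is cut by a gamma renewal process:
fragment lengths are i.i.d. Gamma(shape 9, scale 50) draws (mean 450 bp,
SD 150 bp), rounded to integers, with the final fragment truncated so the
fragments tile the molecule exactly. The three methods share this length
model; enzymatic digestion additionally carries a per-base artifact indel
rate (default 0.001/bp) representing faulty nick repair. Size selection
removes fragments shorter than 500 bp. This renewal model yields the
qualitative coverage phenomenon of interest — short amplicons lose a
disproportionate share of their mass to the <500 bp cut because the
truncated edge fragment is a larger fraction of a short molecule — though
the depletion is milder than in real libraries (see Limitations).

**Sequencing.** One read per retained fragment, taken from a uniformly
chosen fragment end (reverse-complemented for the 3' end). The read's
reference span is min(fragment length, N(450, 120) truncated at 1);
median read length lands near 450 bp, matching the platform. Errors:

* *Homopolymer miscalls*: each maximal run of n ≥ 2 identical bases is
  emitted with length n±1 with probability min(hp_beta·n, hp_pmax),
  split evenly between +1 and −1 (the platform literature describes the
  mechanism, not the sign distribution; symmetry is our choice). Default
  hp_beta = 0.01, hp_pmax = 0.5, which gives ≈0.45%/bp raw indel calls on
  random DNA — a realistic raw pyrosequencing indel rate.
* *Substitutions*: per-base rate sub_rate0 + sub_rate_slope·(i/L) ramping
  along the read (defaults 0.002 and 0.003).
* *Qualities*: round(q0 − q_decay·(i/L)^q_gamma) plus ±2 integer noise,
  floored at 2 (defaults q0 = 38, q_decay = 20, q_gamma = 1.7), written in
  Sanger (offset-33) FASTQ encoding. Qualities are decorative — they decay
  like real 3' ends but are not calibrated to the injected error rates.

**Barcodes and truth.** Each read gets a 10 bp MID prepended (nine fixed
barcodes, pairwise Hamming distance ≥ 5). With probability 0.025 the MID is
replaced by random bases, creating a clean unassignable channel at the
observed real-run rate of ~2.5%. Every read records its sample, amplicon,
reference interval, strand and an edit string (`=/X/I/D` with explicit
bases), so that replaying the edits against the reference reconstructs the
read exactly — the invariant every simulation test relies on. Planted
heterozygous SNPs are applied per molecule (each molecule draws an allele
at 50%) and appear in the truth edit string as substitutions against the
reference.

**Run scale.** The default `molecules_per_amplicon = 360` with nine samples
yields ≈130,000 reads, the scale of the real run this emulates. Tests and
the acceptance script use scaled-down molecule counts (typically 8–330 per
amplicon, chosen so that coverage sits where each scenario needs it, e.g.
~100x for rate recovery); the statistics of interest are per-position
rates, which are insensitive to run scale beyond their sampling noise.

## Demultiplexing (demux)

Prefix Hamming distance against all barcodes; a read is assigned to the
unique barcode within `max_mismatch` (default 1; the barcode set supports
this because pairwise distances exceed 2·max_mismatch), and UNASSIGNED on
ties or misses. Barcodes are stripped and qualities trimmed in lockstep
before analysis.

## Alignment and pileup (pileup)

Simulated runs are analysed on their truth alignments — exact by
construction. The built-in aligner (semi-global: read end-to-end, free
reference ends; affine gaps with match +1, mismatch −3, gap open −5, gap
extend −2; a gap of length g costs open + g·extend) exists to ingest
reads without truth and is validated against a brute-force DP oracle and
against truth pileups on error-free runs. It is implemented as full
row-vectorized dynamic programming rather than the banded variant
originally planned: at the scales it is used (reads vs. single amplicons)
full DP is fast and avoids seeding heuristics. External SAM is ingested
with pysam, with CIGAR `M` resolved to `=`/`X` against the reference.

Pileup conventions (the standard dialect): every `=`/`X` adds one base
call at its position; a deletion adds one deletion call at every deleted
position, so deleted bases count toward depth; insertions anchor to the
preceding reference position and do not add depth. Indels whose bases form
a single homopolymer are left-normalized to their leftmost equivalent
placement so that equivalent observations aggregate at one locus; truth
and aligner routes therefore produce identical pileups in the cases the
tests compare.

## Raw error statistic (errorstats)

Unfiltered pileups only. A position is *eligible* when depth ≥ min_depth
(default 20) and (depth − major)/depth < max_alt_freq (default 0.20),
where the major allele is the largest of the base counts and the deletion
count. The depth threshold is "≥ 20"; the source material is ambiguous
between ≥ 20 and > 20, so the value is configurable. At eligible
positions: calls equal to the reference or the major allele are correct
(ties toward the reference); other base calls are missense errors;
deletion calls are deletion errors unless deletion *is* the major allele
(then deletions are correct and only reference-matching base calls are
correct among bases — a convention we had to define, as rare true
deletions are otherwise uninterpretable); every anchored insertion event
is an insertion error and enters the shared denominator, except that a
position where one identical insertion is carried by a majority of reads
is ambiguous and ineligible. Percentages are per class over
correct + missense + insertion + deletion calls.

Method comparison uses a two-sample t-test on the three replicate
percentages per class. The choice of test is ours — the source never
names one — and with n = 3 per group it is indicative rather than
rigorous; zero-variance groups are reported as degenerate (±inf statistic)
instead of being tested, and single-replicate groups as not-testable. No
multiple-testing correction is applied across the nine class/pair tests.

## Genotyping and concordance (genotyping)

Indel observations at positions inside (or insertions anchored abutting)
homopolymer runs ≥ hp_min_run (default 5) are removed from the calling
view; base counts are untouched, and reports print the *pre-filter*
counts while calling the genotype on the filtered view — mirroring the
behavior of the variant caller the benchmark table was produced with,
which prints allele counts before its homopolymer filter but calls
afterwards. Note this hard filter *emulates* that caller's homopolymer
handling (indel-call suppression at long runs); the original implements a
quality-model coefficient, not a hard exclusion.

Calling uses one threshold: major-allele frequency f ≥ 0.8 → homozygous,
otherwise heterozygous major|second (lexicographic tie-breaks; deletion
may be an allele, rendered `[]`). The 0.8/0.2 boundary reuses the
"unambiguous genotype" threshold of the error statistic; the original
caller's internal rule is unknown, so this is an explicit, documented
reinterpretation. Replicates pool by summing depths and
coverage-weighting the per-replicate major-allele percentages, rounded
half-away-from-zero — exactly reproducing the published pooled rows that
are internally consistent (753/51%, 729/63%, 779/51%, 138/49%). Three
published rows are *not* the sum of their replicate columns (the
dinucleotide footnote convention and one off-by-one); those printed
values are stored verbatim in `datasets` and never asserted as sums.

Dinucleotide loci are compared jointly: each position is called
separately, locus alleles are the per-position alleles concatenated
(major with major, second with second), the reported Σ is the mean
coverage over both positions and the percentage uses all counts of both.
A locus with zero coverage is a no-call, never a discordance.

## Profiles (profiling)

Coverage: per-position depth and per-amplicon mean/median; overlap
positions count for every covering amplicon (per-amplicon attribution is
our convention; the source plots coverage positionally). Quality: reads
are anchored at their 3' ends, per-position means are averaged in 5-bp
windows, and mean ± SD is taken across replicate groups. Read lengths:
50-bp bins with median/mean/SD and the mode on raw integer lengths.

## Pipeline determinism

All randomness flows from one integer seed through a `SeedSequence` tree
(one child per sample plus one for the final interleaving shuffle), so a
fixed configuration gives byte-identical outputs, which the manifest's
SHA-256 file checksums make easy to verify; manifests contain no
timestamps for this reason. Stage timing goes to stderr only.

## What the simulator does and does not establish

Passing tests show that the statistics are computed correctly and that
the pipeline recovers the parameters and qualitative mechanisms it
injects: substitution-rate recovery, excess enzymatic indels, the
size-selection coverage bias and its removal, and the direction of
homopolymer filtering. They do not validate the simulator against real
454 data: flow-space signals, emPCR duplicates, chimeras, context-biased
substitutions and calibrated qualities are all absent, the coverage
depletion of short amplicons is milder than observed in real libraries,
and the per-method read-length differences of real runs (medians
455/451/441 bp) are not modelled — all methods share one fragment-length
distribution, differing only in the enzymatic artifact indel rate.
Consequently the absolute error percentages of a real instrument run are
out of reach by design; only numbers derived from the bundled printed
table are comparable to published values.
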