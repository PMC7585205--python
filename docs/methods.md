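# Methods

This note documents the models and procedures implemented in pegsplice,
their parameters and defaults, what the synthetic-data generator does and
does not emulate, and the numerical and design choices made where the
underlying analysis left the design open.

## Coordinates and data model

All genomic coordinates are 0-based half-open in memory; GTF/GFF3 I/O
converts from/to the 1-based inclusive convention. An isoform is an
ordered, non-overlapping exon chain on one strand; the derived intron
chain (gaps between consecutive exons) is the isoform's identity for
collapse and the site source for AS comparison. Intron lengths are
constrained to [20, 20 000] nt — the upper bound mirrors common long-read
aligner settings for mid-transcript introns, the lower bound excludes
alignment artifacts. Splice-site kinds are strand-aware: the donor is the
transcript-5′ boundary of an intron, the acceptor the transcript-3′
boundary.

## Read classification

A read of insert is classified from three signals:

- **Primer hits.** Each primer and its reverse complement is matched
  semi-globally with edlib (edit distance, indels allowed), accepting hits
  within `max_mismatch_fraction` (default 0.1) of the primer length. Since
  only best-distance hits are reported per search, found regions are
  masked and the search repeated, so internal copies at worse distance are
  still found. Hits within 100 nt of a read end (`terminal_margin`) are
  terminal; all others are internal. Reads in antisense orientation are
  reverse-complemented before classification.
- **Poly(A) tail.** The explicit tail rule (below) applied to the region
  5′ of the 3′-primer hit, so read classification and poly(A) analysis
  share one tail definition.
- **Chimera flag.** Any internal primer hit marks the read as a
  concatemer. FL requires both terminal primers and a tail simultaneously;
  FLNC is FL and non-chimeric.

Summaries report per-sample and total counts with percentages to two
decimals (half-up rounding, as report tables are conventionally printed);
the identities `FL + nFL = total` and `FLNC + chimeric = FL` are validated
on construction, and `ClassificationSummary.from_counts` can derive FL
from FLNC + chimeric when building a summary from published totals.

## Isoform collapse

Alignments below coverage 0.8 or identity 0.7 are dropped (the `-c/-i`
convention of long-read collapse tools). Surviving multi-exon alignments
are mergeable when their intron chains are identical and their transcript
5′/3′ ends differ by at most 1000/100 nt — tolerant 5′ ends reflect 5′
degradation of long reads. Single-exon alignments are mergeable at
reciprocal overlap ≥ 0.5. The merge relation is closed transitively
(single-linkage over the pairwise relation on the original alignments);
this makes the result well-defined and order-independent, unlike
fixpoint merging on cluster bounds, which depends on merge order. Each
component becomes one isoform with the outermost observed boundaries and
a support count equal to the component size; isoforms then group into
genes by span overlap on the same strand and are named `PB.<gene>.<iso>`.

## AS event typing

Two isoforms of a gene are compared over their shared genomic span
[max(starts), min(ends)). Only introns fully contained in that span
contribute sites; shared sites (same position and kind) partition the
span into bubbles, and every bubble containing differing sites yields one
event. A bubble crossed by an intron that extends past the shared span is
discarded — such differences are terminal (alternative first/last exons,
TSS/TES shifts), not splicing events. Templates:

| type | variant chains (transcript order) | extra condition |
|------|------------------------------------|-----------------|
| IR   | `^-` vs empty | empty chain exonic across the intron |
| ES   | `-^` vs empty | empty chain intronic across the exon |
| AA   | `-` vs `-`    | — |
| AD   | `^` vs `^`    | — |
| MX   | `-^` vs `-^`  | alternative exons do not overlap |

Anything else is `other`; complex bubbles are never forced into one of
the five types. Codes are generated generically: the union of variant
sites is numbered in transcript order, each chain lists its numbered
sites (`^` donor, `-` acceptor), the chain holding site 1 prints first
and an empty chain prints as `0`. This reproduces the canonical codes
(`1^2-,0`, `1-2^,0`, `1-,2-`, `1^,2^`, `1-2^,3-4^`) and extends to
`other` bubbles. ASCII hyphens are emitted where typography sometimes
uses en-dashes. Per-gene events are the union over transcript pairs
deduplicated by (type, flanks, variant sites): the same physical bubble
seen in several pairs counts once. Because grouping granularity differs
between tools, absolute event totals are not comparable across
implementations; summaries are validated against planted synthetic truth
and against printed summary arithmetic instead.

Isoform-count comparison between two annotations reports
log2(n_query/n_reference) per shared gene with groups I (≤ −1, fewer),
II ((−1, 1), comparable) and III (≥ +1, more).

## Poly(A) analysis

The tail rule — more than eight A and fewer than two non-A bases within
the terminal 30 bases — is implemented as the longest suffix of length
≤ 30 with ≥ 9 A and ≤ 1 non-A; the wording is ambiguous about fixed
window versus suffix, and the suffix reading is flagged as interpretive
(it makes tail length well-defined and monotone). Windows shorter than
30 bases at the read end are inspected as-is.

The cleavage site is the genomic coordinate of the last transcribed base
before the tail: the rightmost aligned base for + strand, leftmost for −.
Sites are assigned to the nearest same-strand gene whose span extended by
the merge window contains them, and merge within a gene at ≤ 24 nt
(single-linkage along sorted positions; 24 nt is standard
alternative-polyadenylation clustering practice and configurable). The
merged position is the support-weighted mode (ties to the smaller
coordinate) and support is summed, so clustering is input-order
invariant. Nucleotide profiles cover −50..+50 in transcript orientation
(− strand windows reverse-complemented); sites within 50 nt of a
chromosome edge are excluded and counted. Motif occurrence (AAUAAA,
UGUA, matched on DNA with T≡U) is exact-match counting in the 50-nt
upstream window — de-novo motif discovery is out of scope.

## Junction consensus

Junctions are keyed by exact (chrom, strand, donor, acceptor); no fuzz
window. The retention rule is ≥ 2 sources and ≥ 5 reads. Support
aggregates across sources by **maximum**: the callers align the same
short-read library, so summing would double-count reads; maximum is
conservative. Misordered donor/acceptor pairs are normalized with a
warning. Retention is monotone in sources and support and invariant to
source order.

## Specificity and trends

For an isoform with non-negative tissue pattern normalized to *p*, the
score against tissue *t* is `1 − sqrt(JSD(p, e_t))` with base-2 entropy
and `0·log 0 := 0`, so scores lie in [0, 1] and equal 1 exactly when
expression is confined to one tissue. The JSD is implemented in-package
(it is part of the score definition) and cross-checked in tests against
an independent library implementation. All-zero vectors are undefined
and excluded from score distributions; argmax ties break
lexicographically. Distributions are compared with the asymptotic
two-sample Kolmogorov–Smirnov test.

Presence for exclusivity is any sample of a group at abundance ≥ 0.1
(FPKM-like; "detected" thresholds are rarely published — configurable).
Differential selection across stages uses a stand-in rule —
max/min stage-mean fold change ≥ 2 with max stage mean ≥ 1.0 — documented
as a substitute, not a reproduction of any specific test. Time-course
clustering z-scores each profile and runs seeded k-means (k = 2,
k-means++ with 10 restarts), then relabels clusters `up`/`down` by the
sign of the mean first-to-last z difference; fuzzy time-course clustering
would serve equally, but only the up/down partition is consumed
downstream. Constant profiles are excluded and logged.

## Synthetic data

The generator emulates the study conditions of an eight-library
long-read + short-read experiment: samples are four tissues (root, leaf,
shoot tip, flower) plus four peg stages (S1–S4, jointly the "peg"
tissue), one library each. Defaults: non-full-length read fraction 0.18
and chimera fraction 0.06 of FL reads (matching run-report proportions of
this kind of experiment), per-base substitution error 0.01 (CCS-like
accuracy; indels optional and off by default), tail length ~ N(30, 5)
truncated at 15. Genomes are i.i.d. uniform with optional GC bias; desk
scale is 2 × 500 kb and 100 genes (5–8 exons of 120–300 nt, introns
250–1200 nt), sized so the default planted design (IR 4, ES 3, AA 3,
AD 3, MX 2 — one or two events per gene at introns separated by at least
one shared intron, keeping deduplicated counts exact) and the expression
design (8 exclusives per non-peg tissue, 6 per stage, 25 up + 25 down
trends, remainder shared) both fit. Canonical GT..AG dinucleotides are
written at every intron boundary. Primer sequences are two fixed
package-invented 24-mers. Every generator is bit-reproducible under
(config, seed), and a truth manifest labels every read, event, cleavage
site, junction and expression pattern exactly once.

What the simulator does **not** emulate: realistic long-read error
profiles (no homopolymer bias, no quality-value model), alignment
ambiguity (truth alignments are exact exon footprints), overlapping
genes, paralogy, incomplete splicing intermediates, and library-size or
batch effects in expression. Passing the planted-recovery suites
therefore demonstrates correctness of the operators under their stated
assumptions, not robustness to every artifact of real data.

## Numerical choices

Percentages print to two decimals with half-up rounding. ORF search
scans the three forward frames of the oriented transcript only
(transcripts are stranded), requires ATG..stop with no N codon inside,
counts length in amino acids excluding the stop, and breaks ties toward
the 5′-most start; the default minimum is 100 aa. Novel-intergenic
detection is strand-agnostic any-overlap (≥ 1 bp of any exon against a
reference gene span). Fusion candidates need ≥ 2 segments each covering
≥ 5% of the read mapping to distinct loci (different chromosomes or
> 100 kb apart); no summed-coverage requirement is imposed by default
(`min_total_coverage` is available), and the class is interchromosomal
iff segments span two or more chromosomes.

## Problem sizes

Tests and the acceptance script run at desk scale by design: ~100-gene
genomes, a few hundred simulated reads, and exhaustive AS-classifier
enumeration on an 8-boundary coordinate grid (all transcript pairs with
≤ 4 exons, >8 000 pairs) cross-checked against a brute-force per-base
template matcher. These sizes exercise every code path while keeping the
full suite under a minute.

## Known limitations

- Event totals depend on pair-dedup granularity and are not comparable
  across tools; only planted-truth counts and printed-ratio arithmetic
  are asserted.
- The collapse end-tolerance defaults (1000/100 nt) are long-read
  practice, not fitted values.
- Junction identity has no fuzz window; callers that shift boundaries by
  a base will not merge.
- The differential-selection rule is a documented stand-in.
- Primer detection assumes primers are distinguishable from the insert
  at the configured edit distance; extremely short or low-complexity
  primers would degrade chimera detection.
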