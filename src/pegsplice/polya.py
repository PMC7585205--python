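"""Poly(A) tail calling, cleavage-site mapping, per-gene site clustering and
flanking-sequence profiling.

The tail-calling rule inspects the terminal window of up to 30 bases of a
read and accepts the longest suffix containing more than eight A bases and
fewer than two non-A bases. The cleavage site is the genomic coordinate of
the last transcribed base before the untemplated tail: the rightmost aligned
base for + strand transcripts, the leftmost for - strand.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .annotation import AlignedTranscript, AnnotationSet
from .utils import revcomp, round_half_up

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "U")


@dataclass(frozen=True)
class TailCall:
    """A called poly(A) tail in read coordinates."""

    tail_start: int
    tail_length: int
    non_a_count: int
    read_id: str | None = None


@dataclass(frozen=True)
class PolyASite:
    """A genomic cleavage position with read support."""

    chrom: str
    strand: str
    cleavage_position: int
    support: int = 1
    gene_id: str | None = None


def call_tail(
    sequence: str,
    window: int = 30,
    min_a: int = 9,
    max_non_a: int = 1,
    read_id: str | None = None,
) -> TailCall | None:
    """Call a poly(A) tail on the 3' end of ``sequence``.

    The longest suffix of length <= ``window`` with at least ``min_a`` A
    bases and at most ``max_non_a`` non-A bases is the tail ("more than
    eight A and less than two non-A in 30 bases"). Returns None when no
    suffix qualifies.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    limit = min(window, len(seq))
    for length in range(limit, 0, -1):
        suffix = seq[-length:]
        n_a = suffix.count("A")
        if n_a >= min_a and length - n_a <= max_non_a:
            return TailCall(
                tail_start=len(seq) - length,
                tail_length=length,
                non_a_count=length - n_a,
                read_id=read_id,
            )
    return None


def map_cleavage_site(
    alignment: AlignedTranscript, tail: TailCall | None
) -> PolyASite:
    """Map a called tail to its genomic cleavage position.

    + strand: the alignment's rightmost aligned base; - strand: the leftmost.
    """
    if tail is None:
        raise ValueError("cannot map a cleavage site without a called tail")
    model = alignment.model
    position = model.end - 1 if model.strand == "+" else model.start
    return PolyASite(model.chrom, model.strand, position, support=1)


@dataclass
class PolyAClusterResult:
    """Per-gene merged sites plus the site-count distribution."""

    sites_by_gene: dict[str, list[PolyASite]]
    unassigned: list[PolyASite]
    n_genes_total: int

    @property
    def counts_per_gene(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.sites_by_gene.items()}

    @property
    def n_genes_with_site(self) -> int:
        return sum(1 for n in self.counts_per_gene.values() if n >= 1)

    @property
    def n_genes_with_5_sites(self) -> int:
        return sum(1 for n in self.counts_per_gene.values() if n >= 5)

    @property
    def fraction_with_site(self) -> float:
        return self.n_genes_with_site / self.n_genes_total

    @property
    def fraction_with_5_sites(self) -> float:
        return self.n_genes_with_5_sites / self.n_genes_total

    @property
    def mean_sites_per_gene(self) -> float:
        """Mean site count over genes with at least one site, to 2 decimals."""
        counts = [n for n in self.counts_per_gene.values() if n >= 1]
        if not counts:
            return 0.0
        return round_half_up(sum(counts) / len(counts), 2)


def _merge_run(run: list[PolyASite]) -> PolyASite:
    """Merge a cluster of nearby sites; position = support-weighted mode."""
    support_at: Counter[int] = Counter()
    for site in run:
        support_at[site.cleavage_position] += site.support
    position = min(
        support_at, key=lambda p: (-support_at[p], p)
    )  # max support, ties to smallest coordinate
    total = sum(s.support for s in run)
    first = run[0]
    return PolyASite(first.chrom, first.strand, position, total, first.gene_id)


def cluster_sites(
    sites: Sequence[PolyASite],
    annotation: AnnotationSet,
    merge_window: int = 24,
) -> PolyAClusterResult:
    """Assign cleavage sites to genes and merge nearby sites.

    A site is assigned to the nearest same-strand gene whose span, extended
    by ``merge_window``, contains it; unassigned sites are kept separately.
    Within a gene, sites closer than ``merge_window`` (single-linkage along
    the sorted positions) merge into one site whose position is the
    support-weighted mode and whose support is the sum. The result is
    independent of input order.
    """
    assigned: dict[str, list[PolyASite]] = defaultdict(list)
    unassigned: list[PolyASite] = []
    for site in sites:
        genes = annotation.genes_overlapping(
            site.chrom,
            site.cleavage_position - merge_window,
            site.cleavage_position + merge_window + 1,
            strand=site.strand,
        )
        if not genes:
            unassigned.append(site)
            continue

        def distance(g) -> int:
            start, end = g.span
            if start <= site.cleavage_position < end:
                return 0
            return min(
                abs(site.cleavage_position - start),
                abs(site.cleavage_position - (end - 1)),
            )

        gene = min(genes, key=lambda g: (distance(g), g.gene_id))
        assigned[gene.gene_id].append(
            PolyASite(
                site.chrom,
                site.strand,
                site.cleavage_position,
                site.support,
                gene.gene_id,
            )
        )

    merged: dict[str, list[PolyASite]] = {}
    for gene_id in sorted(assigned):
        gene_sites = sorted(
            assigned[gene_id], key=lambda s: (s.strand, s.cleavage_position)
        )
        out: list[PolyASite] = []
        run: list[PolyASite] = []
        for site in gene_sites:
            if run and (
                site.strand != run[-1].strand
                or site.cleavage_position - run[-1].cleavage_position > merge_window
            ):
                out.append(_merge_run(run))
                run = []
            run.append(site)
        if run:
            out.append(_merge_run(run))
        merged[gene_id] = out
    return PolyAClusterResult(
        sites_by_gene=merged,
        unassigned=sorted(
            unassigned, key=lambda s: (s.chrom, s.cleavage_position)
        ),
        n_genes_total=annotation.n_genes,
    )


@dataclass
class PolyAProfile:
    """Per-offset nucleotide frequencies around cleavage sites.

    Offsets run -flank..+flank in transcript orientation (offset 0 is the
    cleavage base); rows of ``frequencies`` follow :data:`NUCLEOTIDES`
    (T is reported as U).
    """

    offsets: np.ndarray
    frequencies: np.ndarray  # shape (2*flank+1, 4)
    n_sites: int
    n_excluded: int = 0

    def frequency(self, offset: int, nucleotide: str) -> float:
        idx = int(np.where(self.offsets == offset)[0][0])
        return float(self.frequencies[idx, NUCLEOTIDES.index(nucleotide)])


def nucleotide_profile(
    sites: Iterable[PolyASite],
    genome: Mapping[str, str],
    flank: int = 50,
) -> PolyAProfile:
    """Nucleotide composition in a +/- ``flank`` window around cleavage sites.

    Sequences are taken in transcript orientation (reverse-complemented for
    - strand sites); sites within ``flank`` of a chromosome edge are
    excluded and counted in ``n_excluded``.
    """
    counts = np.zeros((2 * flank + 1, 4), dtype=float)
    n_sites = 0
    n_excluded = 0
    for site in sites:
        seq = genome[site.chrom]
        pos = site.cleavage_position
        if pos - flank < 0 or pos + flank >= len(seq):
            n_excluded += 1
            continue
        window = seq[pos - flank : pos + flank + 1].upper()
        if site.strand == "-":
            window = revcomp(window)
        n_sites += 1
        for i, base in enumerate(window):
            if base == "T":
                base = "U"
            if base in NUCLEOTIDES:
                counts[i, NUCLEOTIDES.index(base)] += 1
    with np.errstate(invalid="ignore"):
        freqs = counts / counts.sum(axis=1, keepdims=True)
    return PolyAProfile(
        offsets=np.arange(-flank, flank + 1),
        frequencies=freqs,
        n_sites=n_sites,
        n_excluded=n_excluded,
    )


@dataclass
class MotifCounts:
    """Occurrences of upstream motifs around cleavage sites."""

    counts: dict[str, int]
    position_histogram: dict[str, Counter]
    n_sites_with_motif: dict[str, int]
    n_sites: int = 0


def count_motifs(
    sites: Iterable[PolyASite],
    genome: Mapping[str, str],
    motifs: Sequence[str] = ("AAUAAA", "UGUA"),
    upstream_window: int = 50,
) -> MotifCounts:
    """Exact-match occurrences of RNA motifs upstream of cleavage sites.

    Motifs are given in the RNA alphabet and matched against DNA with T==U.
    The upstream window covers offsets ``-upstream_window..-1`` relative to
    the cleavage base, in transcript orientation; histogram offsets are the
    motif start positions.
    """
    dna_motifs = {m: m.upper().replace("U", "T") for m in motifs}
    counts = {m: 0 for m in motifs}
    hist: dict[str, Counter] = {m: Counter() for m in motifs}
    with_motif = {m: 0 for m in motifs}
    n_sites = 0
    for site in sites:
        seq = genome[site.chrom]
        pos = site.cleavage_position
        if site.strand == "+":
            upstream = seq[max(0, pos - upstream_window) : pos].upper()
        else:
            upstream = revcomp(
                seq[pos + 1 : pos + 1 + upstream_window].upper()
            )
        n_sites += 1
        for motif, dna in dna_motifs.items():
            found = False
            start = upstream.find(dna)
            while start != -1:
                counts[motif] += 1
                hist[motif][start - len(upstream)] += 1
                found = True
                start = upstream.find(dna, start + 1)
            if found:
                with_motif[motif] += 1
    return MotifCounts(counts, hist, with_motif, n_sites)


def write_sites_bed(sites: Iterable[PolyASite], path) -> None:
    """Write merged sites as BED6 (1-bp interval, support in the score column)."""
    with open(path, "w") as fh:
        for site in sites:
            name = site.gene_id or "."
            fh.write(
                f"{site.chrom}\t{site.cleavage_position}\t"
                f"{site.cleavage_position + 1}\t{name}\t{site.support}\t"
                f"{site.strand}\n"
            )


def write_profile_tsv(profile: PolyAProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("offset\t" + "\t".join(NUCLEOTIDES) + "\n")
        for i, off in enumerate(profile.offsets):
            row = "\t".join(f"{profile.frequencies[i, j]:.6f}" for j in range(4))
            fh.write(f"{off}\t{row}\n")
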