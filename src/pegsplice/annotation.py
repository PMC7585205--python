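"""Gene and transcript models, GTF/GFF3 I/O, isoform collapse, ORF search,
novel-intergenic and fusion-candidate detection.

Coordinates are 0-based half-open everywhere in memory; GTF/GFF3 I/O converts
from/to the 1-based inclusive convention of those formats.
"""

from __future__ import annotations

import logging
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from intervaltree import IntervalTree

from .utils import revcomp

logger = logging.getLogger(__name__)

#: intron-length bounds enforced on every TranscriptModel; the upper bound
#: mirrors common long-read aligner settings for mid-transcript introns.
MIN_INTRON = 20
MAX_INTRON = 20_000

STRANDS = ("+", "-")


class AnnotationError(ValueError):
    """Raised for malformed annotation records or violated model invariants."""


@dataclass(frozen=True, order=True)
class ExonInterval:
    """A genomic exon: 0-based half-open [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise AnnotationError("exon chrom must be non-empty")
        if not self.start < self.end:
            raise AnnotationError(
                f"exon start must be < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise AnnotationError(f"unknown strand symbol {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "ExonInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class TranscriptModel:
    """An isoform as an ordered, non-overlapping exon chain on one strand.

    The intron chain (gaps between consecutive exons) is the identity used by
    collapse and by AS-event comparison.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[ExonInterval, ...]
    support: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(self.exons))
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        if self.strand not in STRANDS:
            raise AnnotationError(f"unknown strand symbol {self.strand!r}")
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.chrom or exon.strand != self.strand:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon on {exon.chrom}{exon.strand} "
                    f"does not match transcript {self.chrom}{self.strand}"
                )
            if prev_end is not None:
                if exon.start < prev_end:
                    raise AnnotationError(
                        f"overlapping exons in transcript {self.transcript_id}"
                    )
                intron_len = exon.start - prev_end
                if not MIN_INTRON <= intron_len <= MAX_INTRON:
                    raise AnnotationError(
                        f"transcript {self.transcript_id}: intron length {intron_len} "
                        f"outside [{MIN_INTRON}, {MAX_INTRON}]"
                    )
            prev_end = exon.end

    # -- derived geometry -------------------------------------------------

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Ordered intron intervals (0-based half-open) between exons."""
        return tuple(
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return self.introns

    def splice_sites(self) -> list[tuple[int, str]]:
        """(position, kind) for every intron boundary; kind is strand-aware:
        the donor is the transcript-5' boundary of an intron."""
        sites: list[tuple[int, str]] = []
        for a, b in self.introns:
            if self.strand == "+":
                sites.append((a, "donor"))
                sites.append((b, "acceptor"))
            else:
                sites.append((a, "acceptor"))
                sites.append((b, "donor"))
        return sites

    def is_exonic_across(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely within one exon."""
        return any(e.start <= start and end <= e.end for e in self.exons)

    def is_intronic_across(self, start: int, end: int) -> bool:
        """True if [start, end) lies entirely within one intron."""
        return any(a <= start and end <= b for a, b in self.introns)

    def sequence(self, genome: Mapping[str, str]) -> str:
        """Spliced transcript sequence in 5'->3' orientation."""
        chrom_seq = genome[self.chrom]
        spliced = "".join(chrom_seq[e.start : e.end] for e in self.exons)
        return revcomp(spliced) if self.strand == "-" else spliced


@dataclass
class GeneModel:
    """A gene: one or more isoforms sharing a locus and strand."""

    gene_id: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts.values()}
        strands = {t.strand for t in self.transcripts.values()}
        if len(chroms) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {self.gene_id}: transcripts span multiple chrom/strand"
            )
        for t in self.transcripts.values():
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"transcript {t.transcript_id} carries gene_id {t.gene_id}, "
                    f"expected {self.gene_id}"
                )

    @property
    def chrom(self) -> str:
        return next(iter(self.transcripts.values())).chrom

    @property
    def strand(self) -> str:
        return next(iter(self.transcripts.values())).strand

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(t.start for t in self.transcripts.values()),
            max(t.end for t in self.transcripts.values()),
        )

    @property
    def n_isoforms(self) -> int:
        return len(self.transcripts)


class AnnotationSet:
    """Genes indexed by id and by genomic interval for overlap queries."""

    def __init__(
        self,
        genes: Iterable[GeneModel] = (),
        chromosomes: Iterable[str] | None = None,
    ) -> None:
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._transcript_ids: set[str] = set()
        self._explicit_chromosomes = set(chromosomes) if chromosomes else None
        for gene in genes:
            self.add_gene(gene)

    def add_gene(self, gene: GeneModel) -> None:
        if gene.gene_id in self.genes:
            raise AnnotationError(f"duplicate gene id {gene.gene_id}")
        for tid in gene.transcripts:
            if tid in self._transcript_ids:
                raise AnnotationError(f"duplicate transcript id {tid}")
        self.genes[gene.gene_id] = gene
        self._transcript_ids.update(gene.transcripts)
        start, end = gene.span
        self._trees[gene.chrom].addi(start, end, gene.gene_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return len(self._transcript_ids)

    @property
    def chromosomes(self) -> set[str]:
        if self._explicit_chromosomes is not None:
            return set(self._explicit_chromosomes)
        return {g.chrom for g in self.genes.values()}

    def transcripts(self) -> Iterable[TranscriptModel]:
        for gene in self.genes.values():
            yield from gene.transcripts.values()

    def genes_overlapping(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[GeneModel]:
        hits = [self.genes[iv.data] for iv in self._trees[chrom].overlap(start, end)]
        if strand is not None:
            hits = [g for g in hits if g.strand == strand]
        return sorted(hits, key=lambda g: (g.span, g.gene_id))

    def __iter__(self) -> Iterable[GeneModel]:
        return iter(self.genes.values())

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# GTF / GFF3 I/O
# ---------------------------------------------------------------------------


def _validate_lines(path: Path) -> None:
    """Pre-scan for structurally invalid records, reporting line numbers."""
    problems = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                problems.append(f"line {lineno}: expected 9 columns, found {len(fields)}")
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                problems.append(f"line {lineno}: non-integer coordinates")
                continue
            if start > end:
                problems.append(f"line {lineno}: start > end")
            if fields[2].lower() == "exon" and fields[6] not in STRANDS:
                problems.append(
                    f"line {lineno}: unknown strand symbol {fields[6]!r}"
                )
    if problems:
        raise AnnotationError(
            "invalid annotation records:\n" + "\n".join(problems)
        )


def _sniff_dialect(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return "gff3"
            if line.startswith("#") or not line.strip():
                continue
            attrs = line.rstrip("\n").split("\t")[-1]
            return "gff3" if ("=" in attrs and '"' not in attrs) else "gtf"
    return "gtf"


def read_annotation(path: str | Path) -> AnnotationSet:
    """Read a GTF or GFF3 file into an :class:`AnnotationSet`.

    GTF exons must carry ``gene_id``/``transcript_id`` attributes; GFF3 exons
    are resolved through their ``Parent`` transcript feature. Structural
    problems are reported with line numbers; overlapping exons or unknown
    strands are hard errors naming the transcript.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_lines(path)
    dialect = _sniff_dialect(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons_by_tx: dict[str, list[ExonInterval]] = defaultdict(list)
    tx_gene: dict[str, str] = {}
    tx_order: list[str] = []
    for f in db.features_of_type("exon"):
        if dialect == "gtf":
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes["gene_id"][0]
        else:
            tid = f.attributes["Parent"][0]
            try:
                parent = db[tid]
                gid = parent.attributes.get("Parent", [tid])[0]
            except gffutils.FeatureNotFoundError:
                gid = tid
        if tid not in tx_gene:
            tx_order.append(tid)
        tx_gene[tid] = gid
        exons_by_tx[tid].append(
            ExonInterval(f.seqid, f.start - 1, f.end, f.strand)
        )

    genes: dict[str, GeneModel] = {}
    gene_tx: dict[str, dict[str, TranscriptModel]] = defaultdict(dict)
    for tid in tx_order:
        exons = sorted(exons_by_tx[tid], key=lambda e: e.start)
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=tx_gene[tid],
            chrom=exons[0].chrom,
            strand=exons[0].strand,
            exons=tuple(exons),
        )
        gene_tx[tx_gene[tid]][tid] = model
    for gid, txs in gene_tx.items():
        genes[gid] = GeneModel(gene_id=gid, transcripts=txs)
    return AnnotationSet(genes.values())


def write_annotation(annotation: AnnotationSet, path: str | Path) -> None:
    """Write the GTF dialect emitted by this package (exon lines only).

    ``read_annotation(write_annotation(a))`` reproduces exon coordinates
    bit-exactly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        for gene in sorted(
            annotation.genes.values(), key=lambda g: (g.chrom, g.span, g.gene_id)
        ):
            for tx in sorted(
                gene.transcripts.values(), key=lambda t: (t.start, t.transcript_id)
            ):
                for exon in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";'
                    )
                    if tx.support is not None:
                        attrs += f' support "{tx.support}";'
                    fh.write(
                        "\t".join(
                            [
                                exon.chrom,
                                "pegsplice",
                                "exon",
                                str(exon.start + 1),
                                str(exon.end),
                                ".",
                                exon.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Aligned transcripts and collapse
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedTranscript:
    """A transcript-to-genome alignment footprint plus quality fractions."""

    query_id: str
    model: TranscriptModel
    coverage: float
    identity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0 and 0.0 <= self.identity <= 1.0):
            raise AnnotationError(
                f"alignment {self.query_id}: coverage/identity outside [0, 1]"
            )


ALIGNED_TSV_HEADER = "query_id\tchrom\tstrand\texon_blocks\tcoverage\tidentity"


def write_aligned_transcripts(
    alignments: Iterable[AlignedTranscript], path: str | Path
) -> None:
    """TSV with 0-based half-open exon blocks as 'start-end,start-end'."""
    with open(path, "w") as fh:
        fh.write(ALIGNED_TSV_HEADER + "\n")
        for aln in alignments:
            blocks = ",".join(f"{e.start}-{e.end}" for e in aln.model.exons)
            fh.write(
                f"{aln.query_id}\t{aln.model.chrom}\t{aln.model.strand}\t"
                f"{blocks}\t{aln.coverage:g}\t{aln.identity:g}\n"
            )


def read_aligned_transcripts(path: str | Path) -> list[AlignedTranscript]:
    alignments = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != ALIGNED_TSV_HEADER:
            raise AnnotationError(
                f"unexpected aligned-transcript header: {header!r}"
            )
        for line in fh:
            qid, chrom, strand, blocks, cov, ident = line.rstrip("\n").split("\t")
            exons = tuple(
                ExonInterval(chrom, int(b.split("-")[0]), int(b.split("-")[1]), strand)
                for b in blocks.split(",")
            )
            model = TranscriptModel(qid, qid, chrom, strand, exons)
            alignments.append(
                AlignedTranscript(qid, model, float(cov), float(ident))
            )
    return alignments


def _ends_compatible(
    a: TranscriptModel,
    b: TranscriptModel,
    five_prime_tolerance: int,
    three_prime_tolerance: int,
) -> bool:
    if a.strand == "+":
        five = abs(a.start - b.start)
        three = abs(a.end - b.end)
    else:
        five = abs(a.end - b.end)
        three = abs(a.start - b.start)
    return five <= five_prime_tolerance and three <= three_prime_tolerance


def _reciprocal_overlap(a: TranscriptModel, b: TranscriptModel) -> float:
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / (a.end - a.start), ov / (b.end - b.start))


def mergeable(
    a: AlignedTranscript,
    b: AlignedTranscript,
    five_prime_tolerance: int = 1000,
    three_prime_tolerance: int = 100,
    single_exon_min_overlap: float = 0.5,
) -> bool:
    """Pairwise merge predicate used by collapse (and by the test oracle).

    Multi-exon alignments merge iff their intron chains are identical and
    their transcript 5'/3' ends differ by at most the tolerances (tolerant 5'
    ends reflect degradation of long-read 5' termini). Single-exon alignments
    merge iff their reciprocal overlap is at least ``single_exon_min_overlap``.
    """
    ta, tb = a.model, b.model
    if ta.chrom != tb.chrom or ta.strand != tb.strand:
        return False
    if ta.introns != tb.introns:
        return False
    if not ta.introns:  # both single-exon
        return _reciprocal_overlap(ta, tb) >= single_exon_min_overlap
    return _ends_compatible(ta, tb, five_prime_tolerance, three_prime_tolerance)


def _component_isoform(members: Sequence[AlignedTranscript]) -> TranscriptModel:
    """Merged isoform: outermost observed boundaries around the shared chain."""
    models = [m.model for m in members]
    chrom, strand = models[0].chrom, models[0].strand
    start = min(m.start for m in models)
    end = max(m.end for m in models)
    introns = models[0].introns
    bounds = [start]
    for a, b in introns:
        bounds.extend([a, b])
    bounds.append(end)
    exons = tuple(
        ExonInterval(chrom, bounds[i], bounds[i + 1], strand)
        for i in range(0, len(bounds), 2)
    )
    return TranscriptModel(
        transcript_id="merged",
        gene_id="merged",
        chrom=chrom,
        strand=strand,
        exons=exons,
        support=len(members),
    )


def collapse_transcripts(
    alignments: Sequence[AlignedTranscript],
    min_coverage: float = 0.8,
    min_identity: float = 0.7,
    five_prime_tolerance: int = 1000,
    three_prime_tolerance: int = 100,
    single_exon_min_overlap: float = 0.5,
) -> AnnotationSet:
    """Collapse transcript alignments into unique isoforms.

    Alignments failing the coverage/identity thresholds are dropped. The
    survivors are merged by single-linkage over :func:`mergeable`; each
    connected component becomes one isoform whose exon boundaries are the
    outermost observed and whose ``support`` is the component size. Isoforms
    are then grouped into genes by span overlap on the same strand and named
    ``PB.<gene>.<isoform>``.
    """
    surviving = [
        a
        for a in alignments
        if a.coverage >= min_coverage and a.identity >= min_identity
    ]
    if not surviving:
        return AnnotationSet()

    # union-find over survivors, restricted to (chrom, strand, intron chain)
    parent = list(range(len(surviving)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    groups: dict[tuple, list[int]] = defaultdict(list)
    for idx, aln in enumerate(surviving):
        groups[(aln.model.chrom, aln.model.strand, aln.model.introns)].append(idx)
    for idxs in groups.values():
        for i_pos, i in enumerate(idxs):
            for j in idxs[i_pos + 1 :]:
                if mergeable(
                    surviving[i],
                    surviving[j],
                    five_prime_tolerance,
                    three_prime_tolerance,
                    single_exon_min_overlap,
                ):
                    union(i, j)

    components: dict[int, list[AlignedTranscript]] = defaultdict(list)
    for idx in range(len(surviving)):
        components[find(idx)].append(surviving[idx])
    isoforms = sorted(
        (_component_isoform(members) for members in components.values()),
        key=lambda t: (t.chrom, t.start, t.end, t.introns),
    )

    # cluster isoforms into genes by span overlap on the same strand
    gene_parent = list(range(len(isoforms)))

    def gfind(i: int) -> int:
        while gene_parent[i] != i:
            gene_parent[i] = gene_parent[gene_parent[i]]
            i = gene_parent[i]
        return i

    by_locus: dict[tuple[str, str], list[int]] = defaultdict(list)
    for idx, iso in enumerate(isoforms):
        by_locus[(iso.chrom, iso.strand)].append(idx)
    for idxs in by_locus.values():
        for i_pos, i in enumerate(idxs):
            for j in idxs[i_pos + 1 :]:
                a, b = isoforms[i], isoforms[j]
                if a.start < b.end and b.start < a.end:
                    ri, rj = gfind(i), gfind(j)
                    if ri != rj:
                        gene_parent[rj] = ri

    clusters: dict[int, list[TranscriptModel]] = defaultdict(list)
    for idx in range(len(isoforms)):
        clusters[gfind(idx)].append(isoforms[idx])
    ordered = sorted(
        clusters.values(), key=lambda ms: (ms[0].chrom, min(m.start for m in ms))
    )
    genes = []
    for g_num, members in enumerate(ordered, start=1):
        gid = f"PB.{g_num}"
        txs = {}
        for t_num, member in enumerate(
            sorted(members, key=lambda t: (t.start, t.end, t.introns)), start=1
        ):
            tid = f"{gid}.{t_num}"
            txs[tid] = TranscriptModel(
                tid, gid, member.chrom, member.strand, member.exons, member.support
            )
        genes.append(GeneModel(gid, txs))
    return AnnotationSet(genes)


# ---------------------------------------------------------------------------
# ORF search
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class OrfCall:
    """An open reading frame in transcript coordinates.

    ``start``..``end`` spans the start codon through the stop codon
    (half-open), so ``end - start`` is divisible by 3 and
    ``length_aa = (end - start) // 3 - 1`` (the stop codon is not counted).
    """

    transcript_id: str | None
    frame: int
    start: int
    end: int
    length_aa: int


def find_longest_orf(
    sequence: str, min_aa: int = 100, transcript_id: str | None = None
) -> OrfCall | None:
    """Longest forward-frame ORF (ATG..stop) of the oriented transcript.

    Only the three forward frames are scanned (transcripts are stranded).
    Codons containing N are non-coding and break an open frame. Returns None
    when no ORF reaches ``min_aa`` amino acids; ties prefer the 5'-most start.
    """
    seq = sequence.upper()
    best: OrfCall | None = None
    for frame in range(3):
        orf_start: int | None = None
        for i in range(frame, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                orf_start = None
                continue
            if codon in _STOPS:
                if orf_start is not None:
                    length_aa = (i - orf_start) // 3
                    if length_aa >= min_aa:
                        cand = OrfCall(
                            transcript_id, frame, orf_start, i + 3, length_aa
                        )
                        if (
                            best is None
                            or cand.length_aa > best.length_aa
                            or (
                                cand.length_aa == best.length_aa
                                and cand.start < best.start
                            )
                        ):
                            best = cand
                    orf_start = None
            elif codon == "ATG" and orf_start is None:
                orf_start = i
    return best


# ---------------------------------------------------------------------------
# Novel intergenic transcripts
# ---------------------------------------------------------------------------


def identify_novel_intergenic(
    isoforms: AnnotationSet, reference: AnnotationSet
) -> list[TranscriptModel]:
    """Isoforms none of whose exons overlap any reference gene span.

    Overlap is strand-agnostic and any-overlap (>= 1 bp against the gene
    span). Chromosomes absent from the reference namespace are a hard error.
    """
    unknown = sorted(
        {t.chrom for t in isoforms.transcripts()} - reference.chromosomes
    )
    if unknown:
        raise AnnotationError(
            f"chromosomes absent from reference annotation: {', '.join(unknown)}"
        )
    novel = []
    for tx in isoforms.transcripts():
        hit = any(
            reference.genes_overlapping(exon.chrom, exon.start, exon.end)
            for exon in tx.exons
        )
        if not hit:
            novel.append(tx)
    return novel


# ---------------------------------------------------------------------------
# Fusion candidates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignedSegment:
    """One aligned piece of a read: genomic footprint plus read fraction."""

    chrom: str
    start: int
    end: int
    strand: str
    read_fraction: float


@dataclass(frozen=True)
class FusionCandidate:
    read_id: str
    segments: tuple[AlignedSegment, ...]
    fusion_class: str  # 'interchromosomal' or 'intrachromosomal'


def detect_fusion_candidates(
    read_segments: Mapping[str, Sequence[AlignedSegment]],
    min_segment_coverage: float = 0.05,
    min_total_coverage: float = 0.0,
    max_same_locus_gap: int = 100_000,
) -> list[FusionCandidate]:
    """Reads whose alignments split across distinct loci.

    A candidate has >= 2 segments each covering >= ``min_segment_coverage``
    of the read, mapping to >= 2 distinct loci (different chromosomes, or the
    same chromosome separated by more than ``max_same_locus_gap``). The class
    is interchromosomal iff segments span >= 2 chromosomes.
    """
    candidates = []
    for read_id in sorted(read_segments):
        segs = [
            s
            for s in read_segments[read_id]
            if s.read_fraction >= min_segment_coverage
        ]
        if len(segs) < 2:
            continue
        if sum(s.read_fraction for s in segs) < min_total_coverage:
            continue
        # single-linkage locus clustering
        segs = sorted(segs, key=lambda s: (s.chrom, s.start))
        loci: list[list[AlignedSegment]] = []
        for seg in segs:
            placed = False
            for locus in loci:
                if any(
                    seg.chrom == other.chrom
                    and max(seg.start, other.start) - min(seg.end, other.end)
                    <= max_same_locus_gap
                    for other in locus
                ):
                    locus.append(seg)
                    placed = True
                    break
            if not placed:
                loci.append([seg])
        if len(loci) < 2:
            continue
        n_chroms = len({s.chrom for s in segs})
        fusion_class = (
            "interchromosomal" if n_chroms >= 2 else "intrachromosomal"
        )
        candidates.append(FusionCandidate(read_id, tuple(segs), fusion_class))
    return candidates
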