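"""Alternative-splicing event detection and classification.

Two isoforms of a gene are compared over their shared genomic span. Each
maximal "bubble" of differing splice sites flanked by shared sites (or by
the shared-span boundaries) yields one event, typed against the five
canonical templates:

==  =========================  ==========
IR  intron retention           1^2-,0
ES  exon skipping              1-2^,0
AA  alternative acceptor       1-,2-
AD  alternative donor          1^,2^
MX  mutually exclusive exons   1-2^,3-4^
==  =========================  ==========

Codes follow the AStalavista convention: sites are numbered in transcript
order across the union of variant sites, ``^`` marks donors and ``-``
acceptors, and the two variant chains are separated by a comma (an empty
chain is ``0``). ASCII hyphens are used throughout. Bubbles that match no
template are typed ``other``. Terminal-exon differences (alternative
first/last exons, TSS/TES shifts) are not events: only introns fully
contained in the shared span contribute sites, and a bubble whose region is
crossed by an intron extending past the shared span is discarded.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .annotation import AnnotationSet, GeneModel, TranscriptModel
from .utils import percent

logger = logging.getLogger(__name__)

EVENT_TYPES = ("IR", "ES", "AA", "AD", "MX", "other")

CANONICAL_CODES = {
    "IR": "1^2-,0",
    "ES": "1-2^,0",
    "AA": "1-,2-",
    "AD": "1^,2^",
    "MX": "1-2^,3-4^",
}

_SYMBOL = {"donor": "^", "acceptor": "-"}


@dataclass(frozen=True)
class SpliceSite:
    chrom: str
    position: int
    kind: str  # 'donor' | 'acceptor'
    strand: str


@dataclass(frozen=True)
class ASEvent:
    """A localized splicing difference between two isoforms of one gene."""

    gene_id: str
    event_type: str
    code: str
    flank_left: int
    flank_right: int
    variant_sites: tuple[tuple[tuple[int, str], ...], ...]  # per variant chain
    transcript_pair: tuple[str, str]

    @property
    def signature(self) -> tuple:
        """Identity for deduplication across transcript pairs."""
        chains = frozenset(self.variant_sites)
        return (self.event_type, self.flank_left, self.flank_right, chains)


def _scoped_sites(t: TranscriptModel, left: int, right: int) -> list[tuple[int, str]]:
    """Splice sites of introns fully contained in the closed span [left, right]."""
    sites = []
    for a, b in t.introns:
        if left <= a and b <= right:
            if t.strand == "+":
                sites.append((a, "donor"))
                sites.append((b, "acceptor"))
            else:
                sites.append((a, "acceptor"))
                sites.append((b, "donor"))
    return sorted(sites)


def _has_straddling_intron(
    t: TranscriptModel, bubble_left: int, bubble_right: int, left: int, right: int
) -> bool:
    """True if an intron of ``t`` crosses the bubble but sticks out of the
    shared span — such bubbles reflect terminal differences, not events."""
    for a, b in t.introns:
        if a < bubble_right and bubble_left < b:  # overlaps open bubble
            if a < left or b > right:
                return True
    return False


def _transcript_order(sites: Sequence[tuple[int, str]], strand: str):
    return list(sites) if strand == "+" else list(reversed(sites))


def _classify_bubble(
    t1: TranscriptModel,
    t2: TranscriptModel,
    run1: list[tuple[int, str]],
    run2: list[tuple[int, str]],
) -> str:
    """Match one bubble's variant-site pattern against the five templates."""
    strand = t1.strand
    pat1 = "".join(_SYMBOL[k] for _, k in _transcript_order(run1, strand))
    pat2 = "".join(_SYMBOL[k] for _, k in _transcript_order(run2, strand))
    pats = sorted([pat1, pat2])

    if pats == ["", "^-"]:
        inner, other = (run1, t2) if pat1 == "^-" else (run2, t1)
        a, b = sorted(p for p, _ in inner)
        if other.is_exonic_across(a, b):
            return "IR"
        return "other"
    if pats == ["", "-^"]:
        inner, other = (run1, t2) if pat1 == "-^" else (run2, t1)
        a, b = sorted(p for p, _ in inner)
        if other.is_intronic_across(a, b):
            return "ES"
        return "other"
    if pat1 == pat2 == "-":
        return "AA"
    if pat1 == pat2 == "^":
        return "AD"
    if pat1 == pat2 == "-^":
        a1, b1 = sorted(p for p, _ in run1)
        a2, b2 = sorted(p for p, _ in run2)
        if b1 <= a2 or b2 <= a1:  # the alternative exons must not overlap
            return "MX"
        return "other"
    return "other"


def _build_code(
    run1: list[tuple[int, str]], run2: list[tuple[int, str]], strand: str
) -> tuple[str, tuple]:
    """Generic AStalavista-style code; also returns canonically ordered chains.

    Sites across both chains are numbered in transcript order; each chain
    lists its numbered sites; the chain holding site 1 is written first and
    an empty chain is written as ``0`` (second).
    """
    ordered_union = _transcript_order(sorted(set(run1) | set(run2)), strand)
    number = {site: i + 1 for i, site in enumerate(ordered_union)}

    def chain_str(run: list[tuple[int, str]]) -> str:
        if not run:
            return "0"
        return "".join(
            f"{number[site]}{_SYMBOL[site[1]]}"
            for site in _transcript_order(sorted(run), strand)
        )

    s1, s2 = chain_str(run1), chain_str(run2)
    chains = [
        (min(number[s] for s in run) if run else math.inf, s, tuple(sorted(run)))
        for run, s in ((run1, s1), (run2, s2))
    ]
    chains.sort(key=lambda c: (c[0], c[1]))
    code = f"{chains[0][1]},{chains[1][1]}"
    variant_sites = (chains[0][2], chains[1][2])
    return code, variant_sites


def pairwise_events(t1: TranscriptModel, t2: TranscriptModel) -> list[ASEvent]:
    """AS events between two isoforms of the same gene.

    Symmetric: ``pairwise_events(t1, t2)`` and ``pairwise_events(t2, t1)``
    yield identical event sets.
    """
    if t1.gene_id != t2.gene_id:
        raise ValueError(
            f"transcripts {t1.transcript_id}/{t2.transcript_id} belong to "
            "different genes"
        )
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        raise ValueError(
            f"transcripts {t1.transcript_id}/{t2.transcript_id} differ in "
            "chrom/strand"
        )
    left = max(t1.start, t2.start)
    right = min(t1.end, t2.end)
    if left >= right:
        return []

    sites1 = _scoped_sites(t1, left, right)
    sites2 = _scoped_sites(t2, left, right)
    shared = sorted(set(sites1) & set(sites2))

    boundaries = [left] + [p for p, _ in shared] + [right]
    events: list[ASEvent] = []
    set1, set2 = set(sites1), set(sites2)
    for lo, hi in zip(boundaries, boundaries[1:]):
        run1 = [s for s in sites1 if lo < s[0] < hi and s not in set2]
        run2 = [s for s in sites2 if lo < s[0] < hi and s not in set1]
        if not run1 and not run2:
            continue
        if _has_straddling_intron(t1, lo, hi, left, right) or _has_straddling_intron(
            t2, lo, hi, left, right
        ):
            continue
        event_type = _classify_bubble(t1, t2, run1, run2)
        code, variant_sites = _build_code(run1, run2, t1.strand)
        events.append(
            ASEvent(
                gene_id=t1.gene_id,
                event_type=event_type,
                code=code,
                flank_left=lo,
                flank_right=hi,
                variant_sites=variant_sites,
                transcript_pair=tuple(sorted((t1.transcript_id, t2.transcript_id))),
            )
        )
    return events


def gene_events(gene: GeneModel) -> list[ASEvent]:
    """Union of pairwise events over all transcript pairs, deduplicated.

    Events sharing (type, flanks, variant sites) across different pairs are
    reported once; genes with a single transcript contribute nothing.
    """
    txs = sorted(gene.transcripts.values(), key=lambda t: t.transcript_id)
    seen: dict[tuple, ASEvent] = {}
    for i, t1 in enumerate(txs):
        for t2 in txs[i + 1 :]:
            for event in pairwise_events(t1, t2):
                seen.setdefault(event.signature, event)
    return sorted(
        seen.values(), key=lambda e: (e.flank_left, e.flank_right, e.event_type, e.code)
    )


@dataclass
class EventSummary:
    """Per-type event and gene counts with report-style percentages."""

    event_counts: dict[str, int]
    gene_counts: dict[str, int]
    total_events: int
    total_as_genes: int

    @property
    def classified_events(self) -> int:
        """Events falling in one of the five canonical types."""
        return sum(self.event_counts.get(t, 0) for t in EVENT_TYPES if t != "other")

    def event_percent(self, event_type: str) -> float:
        return percent(self.event_counts.get(event_type, 0), self.total_events)

    def gene_percent(self, event_type: str) -> float:
        return percent(self.gene_counts.get(event_type, 0), self.total_as_genes)

    @property
    def classified_percent(self) -> float:
        return percent(self.classified_events, self.total_events)

    @classmethod
    def from_counts(
        cls,
        event_counts: dict[str, int],
        gene_counts: dict[str, int],
        total_events: int | None = None,
        total_as_genes: int | None = None,
    ) -> "EventSummary":
        return cls(
            event_counts=dict(event_counts),
            gene_counts=dict(gene_counts),
            total_events=(
                total_events
                if total_events is not None
                else sum(event_counts.values())
            ),
            total_as_genes=(
                total_as_genes
                if total_as_genes is not None
                else max(gene_counts.values(), default=0)
            ),
        )

    def to_dict(self) -> dict:
        out = {
            "total_events": self.total_events,
            "total_as_genes": self.total_as_genes,
        }
        for t in EVENT_TYPES:
            out[f"{t}_events"] = self.event_counts.get(t, 0)
            out[f"{t}_genes"] = self.gene_counts.get(t, 0)
            if self.total_events:
                out[f"{t}_event_percent"] = self.event_percent(t)
            if self.total_as_genes:
                out[f"{t}_gene_percent"] = self.gene_percent(t)
        return out


def summarize_events(annotation: AnnotationSet) -> EventSummary:
    """Detect and tally AS events across an annotation.

    A gene is counted for a type when it has at least one event of that
    type; percentages use total events and total AS genes as denominators.
    """
    event_counts: dict[str, int] = defaultdict(int)
    gene_types: dict[str, set[str]] = defaultdict(set)
    total_events = 0
    as_genes = set()
    for gene in annotation:
        evts = gene_events(gene)
        if not evts:
            continue
        as_genes.add(gene.gene_id)
        for e in evts:
            event_counts[e.event_type] += 1
            gene_types[gene.gene_id].add(e.event_type)
            total_events += 1
    gene_counts: dict[str, int] = defaultdict(int)
    for types in gene_types.values():
        for t in types:
            gene_counts[t] += 1
    return EventSummary(
        event_counts=dict(event_counts),
        gene_counts=dict(gene_counts),
        total_events=total_events,
        total_as_genes=len(as_genes),
    )


@dataclass(frozen=True)
class IsoformRatioRecord:
    """Isoform-count comparison for one gene between two annotations.

    Group I: log2 ratio <= -1 (fewer isoforms in the query), group III:
    >= +1 (more), group II: in between.
    """

    gene_id: str
    n_isoforms_query: int
    n_isoforms_reference: int
    log2_ratio: float
    group: str


def isoform_count_ratio(
    query: AnnotationSet, reference: AnnotationSet
) -> list[IsoformRatioRecord]:
    """log2(query/reference isoform counts) per shared gene, with grouping."""
    records = []
    for gene_id in sorted(set(query.genes) & set(reference.genes)):
        nq = query.genes[gene_id].n_isoforms
        nr = reference.genes[gene_id].n_isoforms
        if nq == 0 or nr == 0:
            logger.warning("gene %s has zero isoforms in one set; skipped", gene_id)
            continue
        ratio = math.log2(nq / nr)
        if ratio <= -1:
            group = "I"
        elif ratio >= 1:
            group = "III"
        else:
            group = "II"
        records.append(IsoformRatioRecord(gene_id, nq, nr, ratio, group))
    return records


def write_event_table(events: Iterable[ASEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene_id\tevent_type\tcode\tflank_left\tflank_right\t"
            "variant_sites\ttranscripts\n"
        )
        for e in events:
            sites = ";".join(
                ",".join(f"{p}{_SYMBOL[k]}" for p, k in chain)
                for chain in e.variant_sites
            )
            fh.write(
                f"{e.gene_id}\t{e.event_type}\t{e.code}\t{e.flank_left}\t"
                f"{e.flank_right}\t{sites}\t{'|'.join(e.transcript_pair)}\n"
            )
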