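"""Synthetic transcriptome simulation with known ground truth.

The generator emulates the data a full-length-transcriptome AS study
produces: a random genome; multi-exon gene models with variant isoforms
realizing planted AS events of the five canonical types (at canonical GT..AG
boundaries); FLNC-like long reads built as
``5' primer + spliced transcript + poly(A) tail + revcomp(3' primer)`` with
configured non-full-length and chimera fractions and uniform substitution
errors; junction call sets from several imperfect callers; and expression
matrices over tissues and peg developmental stages with planted exclusive
isoforms, monotone trend profiles and lognormal noise.

Every generator is bit-reproducible under (config, seed) and records its
output in a :class:`TruthManifest`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import (
    AlignedTranscript,
    AnnotationSet,
    ExonInterval,
    GeneModel,
    TranscriptModel,
)
from .junctions import JunctionCall
from .reads import ReadOfInsert
from .specificity import ExpressionMatrix
from .utils import revcomp

logger = logging.getLogger(__name__)

#: fixed 24-nt cDNA primers shipped with the package (synthetic sequences)
FIVE_PRIME_PRIMER = "AAGCAGTGGTATCAACGCAGAGTA"
THREE_PRIME_PRIMER = "CGCCTGAGTACTTGCAGTACCGGA"

TISSUES = ("root", "leaf", "shoot_tip", "flower", "peg")
STAGES = ("S1", "S2", "S3", "S4")

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition knobs for the synthetic transcriptome.

    Rates mirror the conditions of an Iso-Seq style experiment: eight
    samples (four tissues plus four peg stages, one library each), a
    non-full-length read fraction of ~18%, a chimera fraction of ~6% of FL
    reads, and CCS-like per-base substitution error of 1%.
    """

    seed: int = 0
    # genome
    n_chromosomes: int = 2
    chromosome_length: int = 500_000
    gc_content: float = 0.5
    # annotation
    n_genes: int = 100
    exon_count_range: tuple[int, int] = (5, 8)
    exon_length_range: tuple[int, int] = (120, 300)
    intron_length_range: tuple[int, int] = (250, 1200)
    intergenic_gap_range: tuple[int, int] = (2000, 4000)
    event_counts: dict[str, int] = field(
        default_factory=lambda: {"IR": 4, "ES": 3, "AA": 3, "AD": 3, "MX": 2}
    )
    # reads
    five_prime_primer: str = FIVE_PRIME_PRIMER
    three_prime_primer: str = THREE_PRIME_PRIMER
    reads_per_transcript: int = 3
    tail_length_mean: float = 30.0
    tail_length_sd: float = 5.0
    tail_length_min: int = 15
    nfl_rate: float = 0.18
    chimera_rate: float = 0.06
    error_rate: float = 0.01
    # expression
    samples_per_group: int = 1
    n_tissue_exclusive: int = 8  # per non-peg tissue; peg = union of stages
    n_stage_exclusive: int = 6  # per peg stage
    n_trend_up: int = 25
    n_trend_down: int = 25
    base_expression: float = 10.0
    lognormal_sigma: float = 0.3
    presence_floor: float = 0.5  # minimum expressed abundance
    # junction call sets
    junction_sources: tuple[str, ...] = ("tophat", "mapsplice", "star")
    junction_sensitivity: float = 0.9
    junction_fp_rate: float = 0.05
    junction_support_range: tuple[int, int] = (5, 50)

    def __post_init__(self) -> None:
        for name in ("nfl_rate", "chimera_rate", "error_rate",
                     "junction_sensitivity", "junction_fp_rate", "gc_content"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass
class TruthManifest:
    """Ground-truth labels for every generated entity.

    Sections are filled by the generator that produced them; ``merge``
    combines manifests from different stages of one simulation.
    """

    events: dict[str, list[dict]] = field(default_factory=dict)
    reads: dict[str, dict] = field(default_factory=dict)
    expression: dict[str, dict] = field(default_factory=dict)
    junctions: list[list] = field(default_factory=list)
    cleavage_sites: dict[str, list] = field(default_factory=dict)

    def merge(self, other: "TruthManifest") -> "TruthManifest":
        self.events.update(other.events)
        self.reads.update(other.reads)
        self.expression.update(other.expression)
        self.junctions.extend(other.junctions)
        self.cleavage_sites.update(other.cleavage_sites)
        return self

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


def generate_genome(config: SimulationConfig) -> dict[str, str]:
    """I.i.d. random genome; GC content is controlled by ``gc_content``."""
    if config.chromosome_length < 10_000:
        raise ValueError("chromosome_length must be >= 10 kb")
    rng = np.random.default_rng([config.seed, 11])
    gc = config.gc_content
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for i in range(config.n_chromosomes):
        seq = rng.choice(_BASES, size=config.chromosome_length, p=probs)
        genome[f"chr{i + 1}"] = "".join(seq)
    return genome


def write_genome_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_genome_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# Annotation with planted AS events
# ---------------------------------------------------------------------------


def _plant_variant(
    base_exons: list[tuple[int, int]],
    event_type: str,
    intron_index: int,
    rng: np.random.Generator,
    strand: str,
) -> tuple[list[tuple[int, int]], dict]:
    """Derive a variant exon chain realizing ``event_type`` at one intron.

    Shifts and inserted exons keep all introns above the minimum length.
    Returns the variant exons plus the truth record (genomic coordinates of
    the varied feature).
    """
    exons = [list(e) for e in base_exons]
    i = intron_index
    intron_start, intron_end = exons[i][1], exons[i + 1][0]
    if event_type == "IR":
        merged = exons[: i] + [[exons[i][0], exons[i + 1][1]]] + exons[i + 2 :]
        record = {"type": "IR", "start": intron_start, "end": intron_end}
        return [tuple(e) for e in merged], record
    if event_type == "ES":
        new_len = 100
        offset = int(rng.integers(60, intron_end - intron_start - new_len - 60 + 1))
        new_exon = [intron_start + offset, intron_start + offset + new_len]
        out = exons[: i + 1] + [new_exon] + exons[i + 1 :]
        record = {"type": "ES", "start": new_exon[0], "end": new_exon[1]}
        return [tuple(e) for e in out], record
    if event_type in ("AA", "AD"):
        delta = int(rng.integers(25, 46))
        # acceptor = transcript-3' intron boundary; donor = transcript-5'.
        shift_end = (event_type == "AA") == (strand == "+")
        if shift_end:
            exons[i + 1][0] = intron_end + delta  # shrink downstream exon
            record_pos = intron_end + delta
        else:
            exons[i][1] = intron_start - delta  # shrink upstream exon
            record_pos = intron_start - delta
        record = {"type": event_type, "start": record_pos, "end": record_pos}
        return [tuple(e) for e in exons], record
    if event_type == "MX":
        # replace exon i+1 with an alternative exon inside the next intron
        nxt_start, nxt_end = exons[i + 1][1], exons[i + 2][0]
        new_len = 120
        offset = int(rng.integers(40, nxt_end - nxt_start - new_len - 40 + 1))
        alt = [nxt_start + offset, nxt_start + offset + new_len]
        out = exons[: i + 1] + [alt] + exons[i + 2 :]
        record = {
            "type": "MX",
            "start": exons[i + 1][0],
            "end": alt[1],
        }
        return [tuple(e) for e in out], record
    raise ValueError(f"unknown event type {event_type}")


def generate_annotation(
    config: SimulationConfig, genome: dict[str, str]
) -> tuple[AnnotationSet, TruthManifest]:
    """Place non-overlapping genes and plant the configured AS events.

    Each gene carries a base isoform; genes hosting events gain one variant
    isoform per event, constructed at a valid position (events within one
    gene are planted at introns separated by at least one shared intron so
    signature deduplication keeps planted counts exact). Canonical GT..AG
    dinucleotides are written into ``genome`` (mutated in place) at every
    intron boundary. Raises when the genome is too small for ``n_genes``.
    """
    rng = np.random.default_rng([config.seed, 23])
    event_list: list[str] = []
    for etype in sorted(config.event_counts):
        event_list.extend([etype] * config.event_counts[etype])
    if len(event_list) > 2 * config.n_genes:
        raise ValueError("too many planted events for n_genes (max 2 per gene)")
    # assign events round-robin: at most 2 per gene, well separated
    per_gene_events: dict[int, list[str]] = {}
    order = [int(i) for i in rng.permutation(len(event_list))]
    for slot, event_idx in enumerate(order):
        per_gene_events.setdefault(slot % config.n_genes, []).append(
            event_list[event_idx]
        )

    chroms = sorted(genome)
    cursors = {c: 1000 for c in chroms}
    genes = []
    manifest = TruthManifest()
    mutable_genome = {c: list(genome[c]) for c in chroms}

    for g_idx in range(config.n_genes):
        gene_id = f"SYN.{g_idx + 1}"
        hosted = per_gene_events.get(g_idx, [])
        n_exons = int(rng.integers(*config.exon_count_range) + 1)
        # MX needs a spacious following intron; widen where events are planted
        exon_lens = rng.integers(*config.exon_length_range, size=n_exons)
        intron_lens = rng.integers(*config.intron_length_range, size=n_exons - 1)
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(exon_lens.sum() + intron_lens.sum())

        chrom = chroms[g_idx % len(chroms)]
        start = cursors[chrom] + int(rng.integers(*config.intergenic_gap_range))
        if start + length + 1000 > len(genome[chrom]):
            placed = False
            for alt in chroms:
                alt_start = cursors[alt] + int(
                    rng.integers(*config.intergenic_gap_range)
                )
                if alt_start + length + 1000 <= len(genome[alt]):
                    chrom, start = alt, alt_start
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "insufficient genome space for gene placement; increase "
                    "chromosome_length or n_chromosomes"
                )
        base_exons: list[tuple[int, int]] = []
        pos = start
        for k in range(n_exons):
            base_exons.append((pos, pos + int(exon_lens[k])))
            pos += int(exon_lens[k])
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        cursors[chrom] = pos

        # choose well-separated middle introns for the hosted events; pick a
        # jointly valid combination so two events never crowd each other
        n_introns = n_exons - 1
        candidates = list(range(1, n_introns - 1))
        valid_combos = [
            combo
            for combo in combinations(candidates, len(hosted))
            if all(b - a >= 2 for a, b in zip(combo, combo[1:]))
        ]
        if not valid_combos:
            raise ValueError("gene too small to host its planted events")
        chosen = list(valid_combos[int(rng.integers(len(valid_combos)))])

        def to_model(tid: str, exon_coords: Sequence[tuple[int, int]]):
            return TranscriptModel(
                tid,
                gene_id,
                chrom,
                strand,
                tuple(ExonInterval(chrom, s, e, strand) for s, e in exon_coords),
            )

        transcripts = {f"{gene_id}.1": to_model(f"{gene_id}.1", base_exons)}
        gene_truth = []
        for v_idx, (etype, intron_idx) in enumerate(zip(hosted, sorted(chosen)), 2):
            variant, record = _plant_variant(
                base_exons, etype, intron_idx, rng, strand
            )
            tid = f"{gene_id}.{v_idx}"
            transcripts[tid] = to_model(tid, variant)
            record["transcripts"] = sorted([f"{gene_id}.1", tid])
            gene_truth.append(record)
        if gene_truth:
            manifest.events[gene_id] = gene_truth
        genes.append(GeneModel(gene_id, transcripts))

    annotation = AnnotationSet(genes, chromosomes=chroms)
    # canonical splice boundaries: GT..AG on +, CT..AC on - (genomic strand)
    for tx in annotation.transcripts():
        for a, b in tx.introns:
            seq = mutable_genome[tx.chrom]
            if tx.strand == "+":
                seq[a], seq[a + 1] = "G", "T"
                seq[b - 2], seq[b - 1] = "A", "G"
            else:
                seq[a], seq[a + 1] = "C", "T"
                seq[b - 2], seq[b - 1] = "A", "C"
    for chrom in chroms:
        genome[chrom] = "".join(mutable_genome[chrom])
    return annotation, manifest


# ---------------------------------------------------------------------------
# FLNC-like reads
# ---------------------------------------------------------------------------


@dataclass
class ReadSimulation:
    reads: list[ReadOfInsert]
    alignments: dict[str, AlignedTranscript]
    manifest: TruthManifest


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return "".join(arr)


def simulate_flnc_reads(
    config: SimulationConfig,
    annotation: AnnotationSet,
    genome: Mapping[str, str],
) -> ReadSimulation:
    """Simulate reads of insert with truth labels.

    A full-length read is ``5' primer + spliced transcript + A-tail +
    revcomp(3' primer)``. With probability ``nfl_rate`` a read drops one of
    the three full-length elements; with probability ``chimera_rate`` a read
    is a concatemer with an internal 5'-primer copy (still full-length by
    its termini). Substitution errors are applied uniformly at
    ``error_rate``. The manifest records every label and, for non-chimeric
    tail-bearing reads, the true cleavage site. Truth alignments (the
    transcript's exon footprint) are returned for non-chimeric reads.
    """
    rng = np.random.default_rng([config.seed, 37])
    sample_labels = [t for t in TISSUES if t != "peg"] + list(STAGES)
    transcripts = sorted(annotation.transcripts(), key=lambda t: t.transcript_id)
    reads: list[ReadOfInsert] = []
    alignments: dict[str, AlignedTranscript] = {}
    manifest = TruthManifest()
    counter = 0
    for tx in transcripts:
        insert = tx.sequence(genome)
        cleavage = tx.end - 1 if tx.strand == "+" else tx.start
        for _ in range(config.reads_per_transcript):
            counter += 1
            read_id = f"read_{counter:06d}"
            sample = sample_labels[int(rng.integers(len(sample_labels)))]
            tail_len = max(
                config.tail_length_min,
                int(round(rng.normal(config.tail_length_mean, config.tail_length_sd))),
            )
            tail = "A" * tail_len
            five = config.five_prime_primer
            three_rc = revcomp(config.three_prime_primer)
            is_chimeric = rng.random() < config.chimera_rate
            is_nfl = (not is_chimeric) and rng.random() < config.nfl_rate
            truth: dict = {
                "transcript_id": tx.transcript_id,
                "gene_id": tx.gene_id,
                "sample": sample,
                "is_chimeric": bool(is_chimeric),
                "tail_length": tail_len,
            }
            if is_chimeric:
                other = transcripts[int(rng.integers(len(transcripts)))]
                seq = (
                    five
                    + other.sequence(genome)
                    + tail
                    + five
                    + insert
                    + tail
                    + three_rc
                )
                truth.update(
                    {
                        "is_full_length": True,
                        "is_flnc": False,
                        "has_five_prime": True,
                        "has_three_prime": True,
                        "has_polya": True,
                    }
                )
            elif is_nfl:
                dropped = ("five_prime", "three_prime", "polya")[
                    int(rng.integers(3))
                ]
                parts = {
                    "five_prime": "" if dropped == "five_prime" else five,
                    "polya": "" if dropped == "polya" else tail,
                    "three_prime": "" if dropped == "three_prime" else three_rc,
                }
                seq = parts["five_prime"] + insert + parts["polya"] + parts["three_prime"]
                truth.update(
                    {
                        "is_full_length": False,
                        "is_flnc": False,
                        "has_five_prime": dropped != "five_prime",
                        "has_three_prime": dropped != "three_prime",
                        "has_polya": dropped != "polya",
                        "dropped": dropped,
                    }
                )
                if dropped != "polya":
                    truth["tail_length"] = tail_len
            else:
                seq = five + insert + tail + three_rc
                truth.update(
                    {
                        "is_full_length": True,
                        "is_flnc": True,
                        "has_five_prime": True,
                        "has_three_prime": True,
                        "has_polya": True,
                        "cleavage_site": [tx.chrom, tx.strand, cleavage],
                    }
                )
                manifest.cleavage_sites.setdefault(tx.transcript_id, [
                    tx.chrom, tx.strand, cleavage
                ])
            seq = _mutate(seq, config.error_rate, rng)
            reads.append(ReadOfInsert(read_id, seq, sample))
            manifest.reads[read_id] = truth
            if not is_chimeric:
                footprint = TranscriptModel(
                    read_id, tx.gene_id, tx.chrom, tx.strand, tx.exons
                )
                alignments[read_id] = AlignedTranscript(
                    read_id, footprint, 1.0, 1.0 - config.error_rate
                )
    return ReadSimulation(reads, alignments, manifest)


def write_reads_fastq(reads: Sequence[ReadOfInsert], path: str | Path) -> None:
    """Constant-quality FASTQ (Q30); read group in the description."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(
                f"@{read.read_id} sample={read.sample_label}\n{read.sequence}\n"
                f"+\n{'?' * len(read.sequence)}\n"
            )


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def simulate_expression(
    config: SimulationConfig, annotation: AnnotationSet
) -> tuple[ExpressionMatrix, TruthManifest]:
    """Expression over 8 sample groups (4 tissues + 4 peg stages).

    Planted labels per isoform: exclusive to one non-peg tissue, exclusive
    to one peg stage, a monotone up/down trend across stages (expressed
    everywhere), or shared background. Abundances are
    ``base_expression * lognormal(0, sigma)`` where expressed and exactly 0
    elsewhere, so zero-noise (sigma = 0) exclusivity is exact.
    """
    rng = np.random.default_rng([config.seed, 53])
    isoforms = sorted(t.transcript_id for t in annotation.transcripts())
    gene_map = {
        t.transcript_id: t.gene_id for t in annotation.transcripts()
    }
    non_peg = [t for t in TISSUES if t != "peg"]
    needed = (
        len(non_peg) * config.n_tissue_exclusive
        + len(STAGES) * config.n_stage_exclusive
        + config.n_trend_up
        + config.n_trend_down
    )
    if needed > len(isoforms):
        raise ValueError(
            f"annotation has {len(isoforms)} isoforms but expression design "
            f"needs {needed}; increase n_genes"
        )
    order = [isoforms[int(i)] for i in rng.permutation(len(isoforms))]
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        chunk = order[cursor : cursor + n]
        cursor += n
        return chunk

    tissue_exclusive = {t: take(config.n_tissue_exclusive) for t in non_peg}
    stage_exclusive = {s: take(config.n_stage_exclusive) for s in STAGES}
    trend_up = take(config.n_trend_up)
    trend_down = take(config.n_trend_down)
    shared = order[cursor:]

    groups = non_peg + list(STAGES)
    samples = []
    sample_tissue = {}
    sample_stage = {}
    for group in groups:
        for rep in range(1, config.samples_per_group + 1):
            name = f"{group}_{rep}"
            samples.append(name)
            sample_tissue[name] = group if group in non_peg else "peg"
            if group in STAGES:
                sample_stage[name] = group

    def abundance(n: int) -> np.ndarray:
        noise = (
            rng.lognormal(0.0, config.lognormal_sigma, size=n)
            if config.lognormal_sigma > 0
            else np.ones(n)
        )
        return np.maximum(config.base_expression * noise, config.presence_floor)

    values = pd.DataFrame(0.0, index=isoforms, columns=samples)
    manifest = TruthManifest()

    def expressed_samples(group_names: Sequence[str]) -> list[str]:
        return [s for s in samples if s.rsplit("_", 1)[0] in set(group_names)]

    for tissue, ids in tissue_exclusive.items():
        cols = expressed_samples([tissue])
        for iso in ids:
            values.loc[iso, cols] = abundance(len(cols))
            manifest.expression[iso] = {"label": "tissue_exclusive", "group": tissue}
    # peg-exclusive isoforms are the stage-exclusives (peg = union of stages)
    for stage, ids in stage_exclusive.items():
        cols = expressed_samples([stage])
        for iso in ids:
            values.loc[iso, cols] = abundance(len(cols))
            manifest.expression[iso] = {"label": "stage_exclusive", "group": stage}
    trend_ratio = 2.0
    for label, ids in (("up", trend_up), ("down", trend_down)):
        for iso in ids:
            base = config.base_expression * 0.2
            stage_means = [
                base * trend_ratio**k if label == "up" else base * trend_ratio ** (3 - k)
                for k in range(len(STAGES))
            ]
            for tissue in non_peg:
                cols = expressed_samples([tissue])
                values.loc[iso, cols] = abundance(len(cols))
            for stage, mean in zip(STAGES, stage_means):
                cols = expressed_samples([stage])
                noise = (
                    rng.lognormal(0.0, config.lognormal_sigma, size=len(cols))
                    if config.lognormal_sigma > 0
                    else np.ones(len(cols))
                )
                values.loc[iso, cols] = np.maximum(
                    mean * noise, config.presence_floor * 0.1
                )
            manifest.expression[iso] = {"label": f"trend_{label}", "group": "peg"}
    for iso in shared:
        values.loc[iso, samples] = abundance(len(samples))
        manifest.expression[iso] = {"label": "shared", "group": "all"}

    matrix = ExpressionMatrix(values, sample_tissue, sample_stage, gene_map)
    return matrix, manifest


# ---------------------------------------------------------------------------
# Junction call sets
# ---------------------------------------------------------------------------


def true_junctions(annotation: AnnotationSet) -> set[tuple[str, str, int, int]]:
    """(chrom, strand, donor, acceptor) for every annotated intron."""
    out = set()
    for tx in annotation.transcripts():
        for a, b in tx.introns:
            donor, acceptor = (a, b) if tx.strand == "+" else (b, a)
            out.add((tx.chrom, tx.strand, donor, acceptor))
    return out


def simulate_junction_callsets(
    config: SimulationConfig, annotation: AnnotationSet
) -> tuple[dict[str, list[JunctionCall]], TruthManifest]:
    """Per-source junction call sets with configured sensitivity and FPs.

    Each source reports each true junction with probability
    ``junction_sensitivity`` and support drawn uniformly from
    ``junction_support_range``; false junctions (true ones shifted by a
    small offset, unique to their source) are added at ``junction_fp_rate``
    per true junction.
    """
    rng = np.random.default_rng([config.seed, 71])
    truth = sorted(true_junctions(annotation))
    lo, hi = config.junction_support_range
    call_sets: dict[str, list[JunctionCall]] = {}
    for source in config.junction_sources:
        calls = []
        for chrom, strand, donor, acceptor in truth:
            if rng.random() < config.junction_sensitivity:
                support = int(rng.integers(lo, hi + 1))
                calls.append(
                    JunctionCall(chrom, strand, donor, acceptor, support, source)
                )
        n_fp = int(round(config.junction_fp_rate * len(truth)))
        for _ in range(n_fp):
            chrom, strand, donor, acceptor = truth[int(rng.integers(len(truth)))]
            shift = int(rng.integers(3, 50))
            calls.append(
                JunctionCall(
                    chrom,
                    strand,
                    donor + shift if strand == "+" else donor - shift,
                    acceptor + shift if strand == "+" else acceptor - shift,
                    int(rng.integers(1, hi + 1)),
                    source,
                )
            )
        call_sets[source] = calls
    manifest = TruthManifest(junctions=[list(j) for j in truth])
    return call_sets, manifest
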