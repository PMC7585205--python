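"""Shared builders for tests."""

from __future__ import annotations

from pegsplice.annotation import (
    AlignedTranscript,
    AnnotationSet,
    ExonInterval,
    GeneModel,
    TranscriptModel,
)


def tx(
    tid: str,
    blocks,
    gene: str = "G",
    chrom: str = "chr1",
    strand: str = "+",
) -> TranscriptModel:
    exons = tuple(ExonInterval(chrom, s, e, strand) for s, e in blocks)
    return TranscriptModel(tid, gene, chrom, strand, exons)


def aln(
    qid: str,
    blocks,
    coverage: float = 1.0,
    identity: float = 1.0,
    chrom: str = "chr1",
    strand: str = "+",
) -> AlignedTranscript:
    return AlignedTranscript(
        qid, tx(qid, blocks, gene=qid, chrom=chrom, strand=strand), coverage, identity
    )


def gene_of(*transcripts: TranscriptModel) -> GeneModel:
    return GeneModel(
        transcripts[0].gene_id, {t.transcript_id: t for t in transcripts}
    )


def annotation_of(*genes: GeneModel) -> AnnotationSet:
    return AnnotationSet(genes)
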