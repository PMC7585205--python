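"""Annotation I/O, transcript geometry, ORF search, novel/fusion detection."""

import numpy as np
import pytest

from pegsplice.annotation import (
    AlignedSegment,
    AnnotationError,
    AnnotationSet,
    detect_fusion_candidates,
    find_longest_orf,
    identify_novel_intergenic,
    read_annotation,
    write_annotation,
)
from pegsplice.simulate import SimulationConfig, generate_annotation, generate_genome

from _helpers import annotation_of, gene_of, tx

GTF = """\
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
chr1\tsrc\texon\t501\t600\t.\t+\t.\tgene_id "g1"; transcript_id "t2";
"""

GFF3 = """\
##gff-version 3
chr1\tsrc\tgene\t101\t600\t.\t+\t.\tID=g1
chr1\tsrc\tmRNA\t101\t600\t.\t+\t.\tID=t1;Parent=g1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=t1
chr1\tsrc\texon\t301\t600\t.\t+\t.\tParent=t1
"""


class TestReadAnnotation:
    def test_gtf_two_transcripts_with_intron_chains(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(GTF)
        aset = read_annotation(path)
        assert aset.n_genes == 1 and aset.n_transcripts == 2
        gene = aset.genes["g1"]
        assert len(gene.transcripts["t1"].introns) == 2
        assert len(gene.transcripts["t2"].introns) == 1

    def test_one_based_inclusive_converts_to_half_open(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\ts\texon\t101\t200\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
            'chr1\ts\texon\t301\t400\t.\t+\t.\tgene_id "g"; transcript_id "t";\n'
        )
        t = read_annotation(path).genes["g"].transcripts["t"]
        assert [(e.start, e.end) for e in t.exons] == [(100, 200), (300, 400)]
        assert t.introns == ((200, 300),)

    def test_gff3_parent_resolution(self, tmp_path):
        path = tmp_path / "a.gff3"
        path.write_text(GFF3)
        aset = read_annotation(path)
        assert aset.genes["g1"].transcripts["t1"].n_exons == 2

    def test_overlapping_exons_is_hard_error_naming_transcript(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\ts\texon\t100\t200\t.\t+\t.\tgene_id "g"; transcript_id "tbad";\n'
            'chr1\ts\texon\t150\t250\t.\t+\t.\tgene_id "g"; transcript_id "tbad";\n'
        )
        with pytest.raises(AnnotationError, match="tbad"):
            read_annotation(path)

    def test_unknown_strand_reported_with_line_number(self, tmp_path):
        path = tmp_path / "a.gtf"
        path.write_text(
            'chr1\ts\texon\t100\t200\t.\t*\t.\tgene_id "g"; transcript_id "t";\n'
        )
        with pytest.raises(AnnotationError, match="line 1"):
            read_annotation(path)

    def test_roundtrip_reproduces_exon_coordinates(self, tmp_path):
        config = SimulationConfig(seed=5, n_genes=10, chromosome_length=100_000)
        genome = generate_genome(config)
        annotation, _ = generate_annotation(config, genome)
        path = tmp_path / "round.gtf"
        write_annotation(annotation, path)
        back = read_annotation(path)
        assert back.n_transcripts == annotation.n_transcripts
        for t in annotation.transcripts():
            other = None
            for g in back:
                other = g.transcripts.get(t.transcript_id, other)
            assert other is not None
            assert [(e.start, e.end) for e in other.exons] == [
                (e.start, e.end) for e in t.exons
            ]
            assert other.strand == t.strand
        # second write is byte-identical
        path2 = tmp_path / "round2.gtf"
        write_annotation(back, path2)
        assert path.read_text() == path2.read_text()


class TestOrf:
    @staticmethod
    def _orf_seq(n_aa):
        # ATG + (n_aa - 1) GCT codons + TAA stop
        return "ATG" + "GCT" * (n_aa - 1) + "TAA"

    @pytest.mark.parametrize(
        "n_aa,expected", [(100, 100), (99, None), (150, 150)]
    )
    def test_min_length_threshold(self, n_aa, expected):
        call = find_longest_orf("CC" + self._orf_seq(n_aa) + "GG")
        if expected is None:
            assert call is None
        else:
            assert call.length_aa == expected
            assert (call.end - call.start) % 3 == 0

    def test_longest_orf_wins(self):
        seq = self._orf_seq(120) + "CC" + self._orf_seq(150)
        assert find_longest_orf(seq).length_aa == 150

    def test_tie_breaks_to_five_prime_most_start(self):
        seq = self._orf_seq(100) + "C" + self._orf_seq(100)
        call = find_longest_orf(seq)
        assert call.start == 0

    def test_n_codons_break_an_open_frame(self):
        # an N codon in the middle invalidates the long ORF
        broken = "ATG" + "GCT" * 60 + "NNN" + "GCT" * 60 + "TAA"
        assert find_longest_orf(broken) is None


class TestNovelIntergenic:
    def setup_method(self):
        ref_gene = gene_of(tx("r1", [(1000, 1500), (1600, 2000)], gene="ref1"))
        self.reference = AnnotationSet(
            [ref_gene], chromosomes=["chr1"]
        )

    def test_isoform_inside_reference_span_is_not_novel(self):
        iso = annotation_of(gene_of(tx("q1", [(1100, 1300)], gene="q1")))
        assert identify_novel_intergenic(iso, self.reference) == []

    def test_isoform_in_annotation_gap_is_novel(self):
        iso = annotation_of(gene_of(tx("q1", [(5000, 5400)], gene="q1")))
        novel = identify_novel_intergenic(iso, self.reference)
        assert [t.transcript_id for t in novel] == ["q1"]

    def test_single_bp_overlap_is_not_novel(self):
        # reference span is [1000, 2000); exon ending at 1001 overlaps 1 bp
        iso = annotation_of(gene_of(tx("q1", [(900, 1001)], gene="q1")))
        assert identify_novel_intergenic(iso, self.reference) == []

    def test_exon_overlap_not_span_overlap(self):
        # transcript straddles the gene inside a huge intron: exons clear it
        iso = annotation_of(
            gene_of(tx("q1", [(400, 900), (2500, 3000)], gene="q1"))
        )
        novel = identify_novel_intergenic(iso, self.reference)
        assert [t.transcript_id for t in novel] == ["q1"]

    def test_unknown_chromosome_is_hard_error(self):
        iso = annotation_of(gene_of(tx("q1", [(0, 100)], gene="q1", chrom="chrZ")))
        with pytest.raises(AnnotationError, match="chrZ"):
            identify_novel_intergenic(iso, self.reference)

    def test_matches_brute_force_interval_scan(self, rng):
        ref_genes = []
        for i in range(20):
            start = int(rng.integers(0, 90_000))
            ref_genes.append(
                gene_of(tx(f"r{i}", [(start, start + 500)], gene=f"ref{i}"))
            )
        reference = AnnotationSet(ref_genes, chromosomes=["chr1"])
        spans = [g.span for g in ref_genes]
        queries = []
        for i in range(200):
            start = int(rng.integers(0, 95_000))
            queries.append(gene_of(tx(f"q{i}", [(start, start + 300)], gene=f"q{i}")))
        novel = {
            t.transcript_id
            for t in identify_novel_intergenic(annotation_of(*queries), reference)
        }
        expected = {
            f"q{i}"
            for i, q in enumerate(queries)
            if not any(
                q.span[0] < e and s < q.span[1] for s, e in spans
            )
        }
        assert novel == expected


class TestFusionCandidates:
    def test_interchromosomal_candidate(self):
        segs = {
            "r1": [
                AlignedSegment("chr1", 100, 600, "+", 0.4),
                AlignedSegment("chr5", 900, 1400, "+", 0.4),
            ]
        }
        (cand,) = detect_fusion_candidates(segs)
        assert cand.fusion_class == "interchromosomal"

    def test_single_segment_is_not_a_candidate(self):
        segs = {"r1": [AlignedSegment("chr1", 100, 600, "+", 0.9)]}
        assert detect_fusion_candidates(segs) == []

    def test_distant_same_chromosome_is_intrachromosomal(self):
        segs = {
            "r1": [
                AlignedSegment("chr1", 100, 600, "+", 0.5),
                AlignedSegment("chr1", 500_600, 501_000, "+", 0.45),
            ]
        }
        (cand,) = detect_fusion_candidates(segs)
        assert cand.fusion_class == "intrachromosomal"

    def test_nearby_segments_are_one_locus(self):
        segs = {
            "r1": [
                AlignedSegment("chr1", 100, 600, "+", 0.5),
                AlignedSegment("chr1", 5_000, 5_500, "+", 0.45),
            ]
        }
        assert detect_fusion_candidates(segs) == []

    def test_low_coverage_segments_are_ignored(self):
        segs = {
            "r1": [
                AlignedSegment("chr1", 100, 600, "+", 0.9),
                AlignedSegment("chr5", 900, 950, "+", 0.01),
            ]
        }
        assert detect_fusion_candidates(segs) == []
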