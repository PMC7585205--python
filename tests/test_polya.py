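"""Poly(A) tail calling, cleavage-site mapping, clustering and profiling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pegsplice.polya import (
    PolyASite,
    TailCall,
    call_tail,
    cluster_sites,
    count_motifs,
    map_cleavage_site,
    nucleotide_profile,
)
from pegsplice.reads import PrimerConfig, classify_read
from pegsplice.utils import revcomp

from _helpers import aln, annotation_of, gene_of, tx


class TestCallTail:
    def test_thirty_consecutive_a(self):
        tail = call_tail("CGT" * 20 + "A" * 30)
        assert tail.tail_length == 30 and tail.non_a_count == 0

    def test_nine_a_one_g_suffix_qualifies(self):
        tail = call_tail("CGTCGTCGT" + "AAAAGAAAAA")
        assert tail is not None
        assert tail.tail_length == 10 and tail.non_a_count == 1

    def test_eight_a_preceded_by_c_fails(self):
        assert call_tail("CGTCGTCGTC" + "A" * 8) is None

    def test_longest_qualifying_suffix_is_chosen(self):
        # ...G AAAA G AAAAA: suffix of 11 has 9 A / 2 non-A? no: test real case
        seq = "CCCCCCCCCC" + "GAAAAAAAAA" + "AAAAA"  # G then 14 A
        tail = call_tail(seq)
        assert tail.tail_length == 15 and tail.non_a_count == 1

    def test_tail_start_is_read_coordinate(self):
        # the longest qualifying suffix absorbs the single allowed non-A
        seq = "CGT" * 10 + "A" * 12
        tail = call_tail(seq)
        assert tail.tail_length == 13 and tail.non_a_count == 1
        assert tail.tail_start + tail.tail_length == len(seq)

    @given(st.text(alphabet="ACGT", min_size=0, max_size=40))
    def test_nine_trailing_a_always_yield_a_tail(self, prefix):
        assert call_tail(prefix + "A" * 9) is not None

    @given(st.text(alphabet="CGT", min_size=1, max_size=40))
    def test_terminal_window_without_a_yields_none(self, seq):
        assert call_tail(seq) is None


class TestMapCleavageSite:
    def test_plus_strand_uses_rightmost_aligned_base(self):
        alignment = aln("r", [(500, 700), (800, 1000)])
        site = map_cleavage_site(alignment, TailCall(0, 20, 0))
        assert site.cleavage_position == 999 and site.strand == "+"

    def test_minus_strand_uses_leftmost_aligned_base(self):
        alignment = aln("r", [(2000, 2200), (2300, 2500)], strand="-")
        site = map_cleavage_site(alignment, TailCall(0, 20, 0))
        assert site.cleavage_position == 2000 and site.strand == "-"

    def test_missing_tail_is_an_error(self):
        with pytest.raises(ValueError):
            map_cleavage_site(aln("r", [(0, 100)]), None)


class TestClusterSites:
    def _annotation(self):
        return annotation_of(
            gene_of(tx("t1", [(1000, 1400), (1500, 2000)], gene="g1"))
        )

    def test_nearby_sites_merge_with_weighted_mode_position(self):
        sites = [
            PolyASite("chr1", "+", 1990, support=3),
            PolyASite("chr1", "+", 2000, support=1),
        ]
        result = cluster_sites(sites, self._annotation())
        (merged,) = result.sites_by_gene["g1"]
        assert merged.support == 4
        assert merged.cleavage_position == 1990  # highest-support position

    def test_distant_sites_stay_separate(self):
        sites = [
            PolyASite("chr1", "+", 1950),
            PolyASite("chr1", "+", 1990),  # 40 nt apart > 24 window
        ]
        result = cluster_sites(sites, self._annotation())
        assert len(result.sites_by_gene["g1"]) == 2

    def test_result_is_order_invariant(self, rng):
        sites = [
            PolyASite("chr1", "+", int(p), support=int(s))
            for p, s in zip(
                rng.integers(1000, 2020, size=30), rng.integers(1, 5, size=30)
            )
        ]
        base = cluster_sites(sites, self._annotation())
        perm = [sites[i] for i in rng.permutation(len(sites))]
        other = cluster_sites(perm, self._annotation())
        assert {
            g: [(s.cleavage_position, s.support) for s in v]
            for g, v in base.sites_by_gene.items()
        } == {
            g: [(s.cleavage_position, s.support) for s in v]
            for g, v in other.sites_by_gene.items()
        }

    def test_sites_outside_every_gene_are_unassigned(self):
        result = cluster_sites(
            [PolyASite("chr1", "+", 50_000)], self._annotation()
        )
        assert result.sites_by_gene == {} or not result.sites_by_gene.get("g1")
        assert len(result.unassigned) == 1

    def test_planted_sites_recovered_exactly_at_zero_noise(self, small_simulation):
        config, genome, annotation, truth, read_sim = small_simulation
        primers = PrimerConfig(config.five_prime_primer, config.three_prime_primer)
        sites = []
        for read in read_sim.reads:
            cls = classify_read(read, primers)
            if cls.is_flnc and cls.tail_length and read.read_id in read_sim.alignments:
                sites.append(
                    map_cleavage_site(
                        read_sim.alignments[read.read_id],
                        TailCall(0, cls.tail_length, 0),
                    )
                )
        recovered = {(s.chrom, s.strand, s.cleavage_position) for s in sites}
        expected = {tuple(v) for v in read_sim.manifest.cleavage_sites.values()}
        assert recovered == expected


class TestNucleotideProfile:
    def test_single_site_profile_is_one_hot(self):
        genome = {"chr1": "ACGT" * 60}
        site = PolyASite("chr1", "+", 120)
        profile = nucleotide_profile([site], genome, flank=10)
        for offset in range(-10, 11):
            base = genome["chr1"][120 + offset]
            base = "U" if base == "T" else base
            assert profile.frequency(offset, base) == 1.0

    def test_uniform_genome_background_is_near_quarter(self, rng):
        genome = {"chr1": "".join(rng.choice(list("ACGT"), size=60_000))}
        sites = [
            PolyASite("chr1", "+", int(p))
            for p in rng.integers(100, 59_900, size=400)
        ]
        profile = nucleotide_profile(sites, genome)
        se = 3 * np.sqrt(0.25 * 0.75 / 400)
        assert np.all(np.abs(profile.frequencies - 0.25) < se + 0.02)

    def test_minus_strand_profile_matches_reverse_complement_site(self):
        genome_fwd = {"chr1": "ACGT" * 100}
        genome_rev = {"chr1": revcomp(genome_fwd["chr1"])}
        pos = 177
        fwd = nucleotide_profile(
            [PolyASite("chr1", "+", pos)], genome_fwd, flank=20
        )
        rev = nucleotide_profile(
            [PolyASite("chr1", "-", len(genome_rev["chr1"]) - 1 - pos)],
            genome_rev,
            flank=20,
        )
        assert np.allclose(fwd.frequencies, rev.frequencies)

    def test_frequencies_sum_to_one_and_edges_are_excluded(self):
        genome = {"chr1": "ACGT" * 100}
        sites = [PolyASite("chr1", "+", 10), PolyASite("chr1", "+", 200)]
        profile = nucleotide_profile(sites, genome, flank=50)
        assert profile.n_excluded == 1 and profile.n_sites == 1
        assert np.allclose(profile.frequencies.sum(axis=1), 1.0, atol=1e-9)


class TestMotifs:
    def test_planted_motif_found_at_expected_offset(self):
        upstream = "C" * 30 + "AATAAA" + "C" * 14  # motif at offset -20
        genome = {"chr1": "G" * 100 + upstream + "G" * 100}
        site = PolyASite("chr1", "+", 150)  # upstream window = seq[100:150]
        result = count_motifs([site], genome, upstream_window=50)
        assert result.counts["AAUAAA"] == 1
        assert result.position_histogram["AAUAAA"][-20] == 1
        assert result.counts["UGUA"] == 0

    def test_sequence_without_motifs_counts_zero(self):
        genome = {"chr1": "C" * 300}
        result = count_motifs([PolyASite("chr1", "+", 150)], genome)
        assert result.counts == {"AAUAAA": 0, "UGUA": 0}

    def test_planted_frequency_recovered_within_three_se(self, rng):
        n, rate = 500, 0.6
        chrom = list("".join(rng.choice(list("CG"), size=200_000)))
        sites = []
        planted = 0
        for i in range(n):
            pos = 200 + i * 390
            if rng.random() < rate:
                chrom[pos - 25 : pos - 19] = list("AATAAA")
                planted += 1
            sites.append(PolyASite("chr1", "+", pos))
        genome = {"chr1": "".join(chrom)}
        result = count_motifs(sites, genome)
        freq = result.n_sites_with_motif["AAUAAA"] / n
        assert freq == planted / n  # exact: no spurious AATAAA in a C/G genome
        assert abs(freq - rate) < 3 * np.sqrt(rate * (1 - rate) / n)

    def test_minus_strand_upstream_window(self):
        # - strand: upstream is to the genomic right, reverse-complemented
        genome = {"chr1": "G" * 100 + revcomp("AATAAA") + "G" * 100}
        site = PolyASite("chr1", "-", 99)
        result = count_motifs([site], genome, upstream_window=20)
        assert result.counts["AAUAAA"] == 1
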