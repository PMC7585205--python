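"""Call poly(A) tails, map cleavage sites and profile their flanks.

The tail rule accepts the longest terminal suffix (within 30 bases) with
more than eight A and fewer than two non-A bases. Cleavage sites map to
the last aligned base before the tail, cluster per gene within 24 nt, and
their flanking sequence is profiled for nucleotide bias and the canonical
AAUAAA / UGUA polyadenylation motifs.
"""

from pegsplice import PrimerConfig, TailCall, call_tail, classify_read, map_cleavage_site
from pegsplice.polya import cluster_sites, count_motifs, nucleotide_profile
from pegsplice.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_genome,
    simulate_flnc_reads,
)

tail = call_tail("CGATCGATTTGCATGC" + "AAAAGAAAAAAAA")
print(f"tail call: length={tail.tail_length} non_A={tail.non_a_count}")

config = SimulationConfig(seed=21, n_genes=40, chromosome_length=250_000,
                          error_rate=0.0)
genome = generate_genome(config)
annotation, _ = generate_annotation(config, genome)
read_sim = simulate_flnc_reads(config, annotation, genome)
primers = PrimerConfig(config.five_prime_primer, config.three_prime_primer)

sites = []
for read in read_sim.reads:
    cls = classify_read(read, primers)
    if cls.is_flnc and cls.tail_length and read.read_id in read_sim.alignments:
        sites.append(map_cleavage_site(
            read_sim.alignments[read.read_id], TailCall(0, cls.tail_length, 0)))

clusters = cluster_sites(sites, annotation)
print(f"genes with >=1 poly(A) site: {clusters.n_genes_with_site}"
      f"/{clusters.n_genes_total}")
print(f"mean sites per gene (genes with a site): {clusters.mean_sites_per_gene}")

merged = [s for g in clusters.sites_by_gene.values() for s in g]
profile = nucleotide_profile(merged, genome)
print(f"profile over {profile.n_sites} sites; A frequency at the cleavage "
      f"base: {profile.frequency(0, 'A'):.2f} (random genome -> ~0.25)")
motifs = count_motifs(merged, genome)
print(f"upstream motif occurrences: {motifs.counts}")
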