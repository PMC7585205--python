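"""End-to-end pipeline orchestration and report emission.

``run_pipeline`` runs the analysis in its natural order — simulate (or
load) inputs, classify reads, collapse alignments, type AS events, call and
profile poly(A) sites, build the junction consensus, and score specificity —
writing per-stage TSV/JSON reports plus a machine-readable run manifest.
Reruns with an identical config produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotation import collapse_transcripts, write_annotation, write_aligned_transcripts
from .events import summarize_events, write_event_table, gene_events
from .junctions import consensus_filter, write_consensus_tsv, write_junctions_tsv
from .polya import (
    TailCall,
    cluster_sites,
    count_motifs,
    map_cleavage_site,
    nucleotide_profile,
    write_profile_tsv,
    write_sites_bed,
)
from .reads import PrimerConfig, classify_read, summarize_classification
from .simulate import (
    STAGES,
    SimulationConfig,
    generate_annotation,
    generate_genome,
    simulate_expression,
    simulate_flnc_reads,
    simulate_junction_callsets,
    write_genome_fasta,
    write_reads_fastq,
)
from .specificity import (
    exclusive_isoforms,
    select_differential,
    stage_specific,
    timecourse_clusters,
    tissue_specificity_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; unknown config keys are rejected."""

    seed: int = 0
    outdir: str = "pegsplice_out"
    # synthetic input scale
    n_genes: int = 40
    n_chromosomes: int = 2
    chromosome_length: int = 250_000
    reads_per_transcript: int = 3
    # read classification
    max_mismatch_fraction: float = 0.1
    terminal_margin: int = 100
    # collapse
    min_coverage: float = 0.8
    min_identity: float = 0.7
    five_prime_tolerance: int = 1000
    three_prime_tolerance: int = 100
    # poly(A)
    merge_window: int = 24
    # junction consensus
    min_sources: int = 2
    min_reads: int = 5
    # specificity
    presence_threshold: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sim_config(config: PipelineConfig) -> SimulationConfig:
    sim = SimulationConfig(seed=config.seed)
    sim.n_genes = config.n_genes
    sim.n_chromosomes = config.n_chromosomes
    sim.chromosome_length = config.chromosome_length
    sim.reads_per_transcript = config.reads_per_transcript
    # keep the expression design feasible at small gene counts
    n_isoforms_est = config.n_genes + sum(sim.event_counts.values())
    while (
        4 * sim.n_tissue_exclusive
        + 4 * sim.n_stage_exclusive
        + sim.n_trend_up
        + sim.n_trend_down
        > n_isoforms_est
        and sim.n_trend_up > 5
    ):
        sim.n_tissue_exclusive = max(1, sim.n_tissue_exclusive - 1)
        sim.n_stage_exclusive = max(1, sim.n_stage_exclusive - 1)
        sim.n_trend_up -= 1
        sim.n_trend_down -= 1
    return sim


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate inputs and run every stage, writing reports to ``outdir``.

    Returns a dictionary of headline numbers (also written to
    ``run_manifest.json`` beside the per-stage reports).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = _sim_config(config)

    # --- synthetic inputs ------------------------------------------------
    genome = generate_genome(sim)
    annotation, truth = generate_annotation(sim, genome)
    read_sim = simulate_flnc_reads(sim, annotation, genome)
    truth.merge(read_sim.manifest)
    matrix, expr_truth = simulate_expression(sim, annotation)
    truth.merge(expr_truth)
    call_sets, junc_truth = simulate_junction_callsets(sim, annotation)
    truth.merge(junc_truth)

    write_genome_fasta(genome, outdir / "genome.fa")
    write_annotation(annotation, outdir / "annotation.gtf")
    write_reads_fastq(read_sim.reads, outdir / "reads.fastq")
    write_aligned_transcripts(
        read_sim.alignments.values(), outdir / "alignments.tsv"
    )
    for source, calls in call_sets.items():
        write_junctions_tsv(calls, outdir / f"junctions_{source}.tsv")
    matrix.to_tsv(outdir / "expression.tsv", outdir / "samples.tsv")
    truth.to_json(outdir / "truth.json")

    # --- classify --------------------------------------------------------
    primers = PrimerConfig(
        sim.five_prime_primer,
        sim.three_prime_primer,
        config.max_mismatch_fraction,
    )
    classifications = [
        classify_read(read, primers, config.terminal_margin)
        for read in read_sim.reads
    ]
    summary = summarize_classification(classifications)
    summary.to_tsv(outdir / "table1_summary.tsv")

    # --- collapse --------------------------------------------------------
    collapsed = collapse_transcripts(
        list(read_sim.alignments.values()),
        min_coverage=config.min_coverage,
        min_identity=config.min_identity,
        five_prime_tolerance=config.five_prime_tolerance,
        three_prime_tolerance=config.three_prime_tolerance,
    )
    write_annotation(collapsed, outdir / "collapsed.gtf")

    # --- AS events (on the truth annotation, which has gene grouping) ----
    all_events = [e for gene in annotation for e in gene_events(gene)]
    write_event_table(all_events, outdir / "events.tsv")
    event_summary = summarize_events(annotation)
    with open(outdir / "event_summary.json", "w") as fh:
        json.dump(event_summary.to_dict(), fh, indent=1, sort_keys=True)

    # --- poly(A) ---------------------------------------------------------
    cls_by_id = {c.read_id: c for c in classifications}
    sites = []
    for read_id in sorted(read_sim.alignments):
        cls = cls_by_id[read_id]
        if not cls.is_flnc or cls.tail_length is None:
            continue
        tail = TailCall(0, cls.tail_length, 0, read_id)
        sites.append(map_cleavage_site(read_sim.alignments[read_id], tail))
    clusters = cluster_sites(sites, annotation, config.merge_window)
    merged_sites = [
        s for gene_id in sorted(clusters.sites_by_gene)
        for s in clusters.sites_by_gene[gene_id]
    ]
    write_sites_bed(merged_sites, outdir / "polya_sites.bed")
    profile = nucleotide_profile(merged_sites, genome)
    write_profile_tsv(profile, outdir / "polya_profile.tsv")
    motifs = count_motifs(merged_sites, genome)
    polya_stats = {
        "n_sites": len(merged_sites),
        "n_genes_with_site": clusters.n_genes_with_site,
        "n_genes_with_5_sites": clusters.n_genes_with_5_sites,
        "mean_sites_per_gene": clusters.mean_sites_per_gene,
        "motif_counts": motifs.counts,
        "sites_with_motif": motifs.n_sites_with_motif,
    }
    with open(outdir / "polya_stats.json", "w") as fh:
        json.dump(polya_stats, fh, indent=1, sort_keys=True)

    # --- junction consensus ----------------------------------------------
    consensus = consensus_filter(call_sets, config.min_sources, config.min_reads)
    write_consensus_tsv(consensus, outdir / "junction_consensus.tsv")

    # --- specificity -----------------------------------------------------
    js_table = tissue_specificity_table(matrix)
    js_table.to_csv(outdir / "js_scores.tsv", sep="\t")
    venn = exclusive_isoforms(matrix, presence_threshold=config.presence_threshold)
    with open(outdir / "venn_tissue.json", "w") as fh:
        json.dump(venn.combination_counts_json(), fh, indent=1, sort_keys=True)
    stage_excl, stage_genes = stage_specific(
        matrix, STAGES, config.presence_threshold
    )
    with open(outdir / "stage_specific.json", "w") as fh:
        json.dump(
            {
                "isoforms": {s: len(stage_excl.exclusive.get(s, set())) for s in STAGES},
                "genes": stage_genes,
            },
            fh,
            indent=1,
            sort_keys=True,
        )
    diff_ids = select_differential(matrix, STAGES)
    stage_profiles = matrix.stage_means().loc[diff_ids, list(STAGES)]
    clusters_tc = timecourse_clusters(stage_profiles, seed=config.seed)
    pd.DataFrame(
        [
            {"isoform_id": c.isoform_id, "cluster": c.label}
            for c in clusters_tc
        ]
    ).to_csv(outdir / "trend_clusters.tsv", sep="\t", index=False)

    headline = {
        "n_reads": len(read_sim.reads),
        "fl_percent": summary.fl_percent,
        "flnc_percent": summary.flnc_percent,
        "n_collapsed_isoforms": collapsed.n_transcripts,
        "n_as_events": event_summary.total_events,
        "n_polya_sites": len(merged_sites),
        "n_retained_junctions": sum(j.retained for j in consensus),
        "n_trend_clustered": len(clusters_tc),
    }
    run_manifest = {
        "package": "pegsplice",
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_dict(),
        "headline": headline,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=1, sort_keys=True)
    return headline
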