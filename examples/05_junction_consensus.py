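"""Merge splice-junction calls from several callers and apply the
consensus rule: keep a junction when at least two callers report it and at
least five reads support it (support aggregated by maximum)."""

from pegsplice import JunctionCall, consensus_filter

call_sets = {
    "tophat": [
        JunctionCall("chr1", "+", 1000, 1200, read_support=12, source="tophat"),
        JunctionCall("chr1", "+", 3000, 3300, read_support=4, source="tophat"),
    ],
    "mapsplice": [
        JunctionCall("chr1", "+", 1000, 1200, read_support=8, source="mapsplice"),
        JunctionCall("chr1", "+", 5000, 5400, read_support=40, source="mapsplice"),
    ],
    "star": [
        JunctionCall("chr1", "+", 3000, 3300, read_support=4, source="star"),
    ],
}

for junction in consensus_filter(call_sets, min_sources=2, min_reads=5):
    status = "retained" if junction.retained else "dropped"
    print(
        f"{junction.chrom}:{junction.donor_pos}-{junction.acceptor_pos}  "
        f"sources={len(junction.supporting_sources)}  "
        f"max_support={junction.max_support}  -> {status}"
    )
# 1000-1200: 2 sources, 12 reads -> retained.
# 3000-3300: 2 sources but only 4 reads -> dropped.
# 5000-5400: 40 reads but a single source -> dropped.
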