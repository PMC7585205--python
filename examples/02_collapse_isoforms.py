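"""Collapse transcript-to-genome alignments into unique isoforms.

Alignments passing the coverage/identity thresholds (0.8 / 0.7) merge when
their intron chains are identical and their 5'/3' ends agree within the
tolerances; each merged isoform records how many reads support it.
"""

from pegsplice import collapse_transcripts
from pegsplice.annotation import AlignedTranscript, ExonInterval, TranscriptModel


def alignment(qid, blocks, coverage=1.0, identity=1.0):
    exons = tuple(ExonInterval("chr1", s, e, "+") for s, e in blocks)
    model = TranscriptModel(qid, qid, "chr1", "+", exons)
    return AlignedTranscript(qid, model, coverage, identity)


alignments = [
    # three reads of one isoform with ragged 5' ends (same intron chain)
    alignment("read1", [(1000, 1500), (1700, 2200)]),
    alignment("read2", [(1080, 1500), (1700, 2180)]),
    alignment("read3", [(1150, 1500), (1700, 2200)]),
    # a second isoform of the same gene: different intron chain
    alignment("read4", [(1000, 1400), (1700, 2200)]),
    # a low-coverage alignment, dropped by the -c 0.8 filter
    alignment("read5", [(1000, 1500), (1700, 2200)], coverage=0.79),
]

collapsed = collapse_transcripts(alignments)
for gene in collapsed:
    for tx in gene.transcripts.values():
        blocks = ", ".join(f"{e.start}-{e.end}" for e in tx.exons)
        print(f"{tx.transcript_id}: exons [{blocks}]  support={tx.support}")
# read1-3 merge into one isoform with the outermost observed boundaries;
# read4 keeps its own intron chain; read5 never enters the output.
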