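"""Splice-junction consensus across multiple callers.

A junction is retained when at least ``min_sources`` callers report it and
its read support reaches ``min_reads``. Support is aggregated across sources
by maximum, which is conservative against double-counting the same reads
aligned by several tools. Junction identity requires an exact boundary and
strand match.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class JunctionCall:
    """One caller's report of an intron boundary pair.

    ``donor_pos``/``acceptor_pos`` are 0-based intron boundaries; on the +
    strand the donor is the intron start, on the - strand the intron end.
    """

    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    read_support: int
    source: str = ""

    def __post_init__(self) -> None:
        if self.donor_pos == self.acceptor_pos:
            raise ValueError("junction donor and acceptor coincide")
        if self.read_support < 0:
            raise ValueError("read support must be >= 0")


@dataclass(frozen=True)
class ConsensusJunction:
    chrom: str
    strand: str
    donor_pos: int
    acceptor_pos: int
    supporting_sources: frozenset[str]
    support_by_source: tuple[tuple[str, int], ...]
    retained: bool

    @property
    def max_support(self) -> int:
        return max(s for _, s in self.support_by_source)


def _normalize(call: JunctionCall) -> JunctionCall:
    """Enforce the strand convention on donor/acceptor ordering."""
    expected_forward = call.strand == "+"
    is_forward = call.donor_pos < call.acceptor_pos
    if is_forward != expected_forward:
        warnings.warn(
            f"junction {call.chrom}:{call.donor_pos}-{call.acceptor_pos} "
            f"({call.strand}) has donor/acceptor in the wrong order; swapped",
            stacklevel=2,
        )
        return JunctionCall(
            call.chrom,
            call.strand,
            call.acceptor_pos,
            call.donor_pos,
            call.read_support,
            call.source,
        )
    return call


def consensus_filter(
    call_sets: Mapping[str, Iterable[JunctionCall]],
    min_sources: int = 2,
    min_reads: int = 5,
) -> list[ConsensusJunction]:
    """Merge per-source junction calls and apply the consensus rule.

    Returns the full merged table; the retained subset is
    ``[j for j in result if j.retained]``. Result order and content are
    independent of source ordering; duplicate calls within one source keep
    the maximum support.
    """
    if not call_sets:
        raise ValueError("at least one call set is required")
    merged: dict[tuple, dict[str, int]] = defaultdict(dict)
    for source in call_sets:
        for call in call_sets[source]:
            call = _normalize(call)
            key = (call.chrom, call.strand, call.donor_pos, call.acceptor_pos)
            prev = merged[key].get(source, 0)
            merged[key][source] = max(prev, call.read_support)
    out = []
    for key in sorted(merged):
        chrom, strand, donor, acceptor = key
        by_source = merged[key]
        retained = (
            len(by_source) >= min_sources
            and max(by_source.values()) >= min_reads
        )
        out.append(
            ConsensusJunction(
                chrom=chrom,
                strand=strand,
                donor_pos=donor,
                acceptor_pos=acceptor,
                supporting_sources=frozenset(by_source),
                support_by_source=tuple(sorted(by_source.items())),
                retained=retained,
            )
        )
    return out


JUNCTION_TSV_HEADER = "chrom\tdonor\tacceptor\tstrand\tsupport\tsource"


def write_junctions_tsv(calls: Iterable[JunctionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(JUNCTION_TSV_HEADER + "\n")
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.donor_pos}\t{c.acceptor_pos}\t{c.strand}\t"
                f"{c.read_support}\t{c.source}\n"
            )


def read_junctions_tsv(path: str | Path) -> list[JunctionCall]:
    calls = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != JUNCTION_TSV_HEADER:
            raise ValueError(f"unexpected junction header: {header!r}")
        for line in fh:
            chrom, donor, acceptor, strand, support, source = line.rstrip(
                "\n"
            ).split("\t")
            calls.append(
                JunctionCall(
                    chrom, strand, int(donor), int(acceptor), int(support), source
                )
            )
    return calls


def read_star_sj(path: str | Path, source: str = "STAR") -> list[JunctionCall]:
    """Read STAR ``SJ.out.tab``-style junctions.

    Column map: chrom, intron first base (1-based), intron last base
    (1-based), strand code (0 undefined, 1 '+', 2 '-'), intron motif,
    annotated flag, unique-read support, multi-read support, overhang.
    Undefined-strand junctions are skipped with a log message. Unique-read
    counts are used as support.
    """
    strand_map = {"1": "+", "2": "-"}
    calls = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 7:
                raise ValueError(f"{path}: line {lineno}: too few columns")
            chrom, first, last, strand_code = fields[:4]
            if strand_code not in strand_map:
                logger.info("%s: line %d: undefined strand; skipped", path, lineno)
                continue
            strand = strand_map[strand_code]
            intron_start = int(first) - 1  # 0-based inclusive start boundary
            intron_end = int(last)  # 0-based exclusive end boundary
            donor, acceptor = (
                (intron_start, intron_end)
                if strand == "+"
                else (intron_end, intron_start)
            )
            calls.append(
                JunctionCall(chrom, strand, donor, acceptor, int(fields[6]), source)
            )
    return calls


def write_consensus_tsv(junctions: Iterable[ConsensusJunction], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "chrom\tstrand\tdonor\tacceptor\tn_sources\tmax_support\t"
            "sources\tretained\n"
        )
        for j in junctions:
            fh.write(
                f"{j.chrom}\t{j.strand}\t{j.donor_pos}\t{j.acceptor_pos}\t"
                f"{len(j.supporting_sources)}\t{j.max_support}\t"
                f"{','.join(sorted(j.supporting_sources))}\t"
                f"{int(j.retained)}\n"
            )
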