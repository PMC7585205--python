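"""Classification of long reads of insert into FL/nFL/FLNC.

A read is full-length (FL) when it simultaneously carries the 5' primer, the
3' primer and a poly(A) tail; an FL read with any internal primer copy is a
chimera (concatemer) and is excluded from the FLNC set. Primer matching is
semi-global (edlib) with a configurable mismatch fraction; hits within a
terminal margin of either read end count as terminal, all others as internal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .polya import call_tail
from .utils import percent, revcomp, round_half_up

logger = logging.getLogger(__name__)

#: primer hits within this many nt of a read end count as terminal
DEFAULT_TERMINAL_MARGIN = 100

SUMMARY_COLUMNS = [
    "reads_of_insert",
    "five_prime_reads",
    "three_prime_reads",
    "polya_reads",
    "nfl_reads",
    "fl_reads",
    "flnc_reads",
    "chimeric_reads",
]


@dataclass(frozen=True)
class ReadOfInsert:
    read_id: str
    sequence: str
    sample_label: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id} has an empty sequence")
        if set(self.sequence.upper()) - set("ACGTN"):
            raise ValueError(f"read {self.read_id} contains non-ACGTN symbols")


@dataclass(frozen=True)
class PrimerConfig:
    five_prime_primer: str
    three_prime_primer: str
    max_mismatch_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not self.five_prime_primer or not self.three_prime_primer:
            raise ValueError("primers must be non-empty")
        if not 0.0 <= self.max_mismatch_fraction <= 0.3:
            raise ValueError("max_mismatch_fraction outside [0, 0.3]")


@dataclass(frozen=True)
class PrimerHit:
    primer: str  # 'five_prime' | 'three_prime'
    orientation: str  # '+' forward, '-' reverse complement
    start: int
    end: int  # half-open, read coordinates
    edit_distance: int
    location: str  # 'start_terminal' | 'end_terminal' | 'internal'


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    has_five_prime: bool
    has_three_prime: bool
    has_polya: bool
    is_full_length: bool
    is_chimeric: bool
    is_flnc: bool
    trimmed_insert: str
    sample_label: str = ""
    tail_length: int | None = None


def _search_all(query: str, target: str, max_edits: int, max_hits: int = 16):
    """All semi-global hits of ``query`` in ``target`` within ``max_edits``.

    edlib reports only best-distance locations, so found regions are masked
    with N and the search repeated until nothing is left within the budget.
    """
    hits: list[tuple[int, int, int]] = []
    buf = list(target)
    for _ in range(max_hits):
        res = edlib.align(query, "".join(buf), mode="HW", task="locations", k=max_edits)
        if res["editDistance"] < 0:
            break
        taken: list[tuple[int, int]] = []
        for s, e in res["locations"]:
            s = 0 if s is None else s
            e = e + 1
            if any(not (e <= ts or s >= te) for ts, te in taken):
                continue
            # drop near-duplicates of already-masked hits found at worse distance
            if any(abs(s - hs) < len(query) // 2 for hs, _, _ in hits):
                continue
            taken.append((s, e))
            hits.append((s, e, res["editDistance"]))
        if not taken:
            break
        for s, e in taken:
            for i in range(s, e):
                buf[i] = "N"
    return sorted(hits)


def detect_primers(
    read: ReadOfInsert,
    primers: PrimerConfig,
    terminal_margin: int = DEFAULT_TERMINAL_MARGIN,
) -> list[PrimerHit]:
    """Semi-global best matches of each primer and its reverse complement."""
    seq = read.sequence.upper()
    out: list[PrimerHit] = []
    for kind, primer in (
        ("five_prime", primers.five_prime_primer),
        ("three_prime", primers.three_prime_primer),
    ):
        max_edits = int(primers.max_mismatch_fraction * len(primer))
        for orientation, query in (("+", primer.upper()), ("-", revcomp(primer.upper()))):
            for s, e, dist in _search_all(query, seq, max_edits):
                if s < terminal_margin:
                    location = "start_terminal"
                elif e > len(seq) - terminal_margin:
                    location = "end_terminal"
                else:
                    location = "internal"
                out.append(PrimerHit(kind, orientation, s, e, dist, location))
    return sorted(out, key=lambda h: (h.start, h.primer, h.orientation))


def classify_read(
    read: ReadOfInsert,
    primers: PrimerConfig,
    terminal_margin: int = DEFAULT_TERMINAL_MARGIN,
) -> ReadClassification:
    """Classify one read of insert.

    The read is oriented so that the 5' primer sits at the start (reads in
    antisense orientation are reverse-complemented first). Poly(A) presence
    is decided by :func:`pegsplice.polya.call_tail` on the region 5' of the
    3'-primer hit; a chimera is any read with an internal primer hit.
    """
    seq = read.sequence.upper()
    hits = detect_primers(ReadOfInsert(read.read_id, seq), primers, terminal_margin)

    def _has(hit_list, primer, orientation, location):
        return any(
            h.primer == primer and h.orientation == orientation and h.location == location
            for h in hit_list
        )

    sense = _has(hits, "five_prime", "+", "start_terminal") or _has(
        hits, "three_prime", "-", "end_terminal"
    )
    antisense = _has(hits, "three_prime", "+", "start_terminal") or _has(
        hits, "five_prime", "-", "end_terminal"
    )
    if antisense and not sense:
        seq = revcomp(seq)
        hits = detect_primers(ReadOfInsert(read.read_id, seq), primers, terminal_margin)

    five_hits = [
        h
        for h in hits
        if h.primer == "five_prime" and h.orientation == "+" and h.location == "start_terminal"
    ]
    three_hits = [
        h
        for h in hits
        if h.primer == "three_prime" and h.orientation == "-" and h.location == "end_terminal"
    ]
    five_hit = min(five_hits, key=lambda h: (h.edit_distance, h.start), default=None)
    three_hit = min(
        three_hits, key=lambda h: (h.edit_distance, -h.end), default=None
    )

    region_end = three_hit.start if three_hit is not None else len(seq)
    tail = call_tail(seq[:region_end]) if region_end > 0 else None

    has_five = five_hit is not None
    has_three = three_hit is not None
    has_polya = tail is not None
    is_fl = has_five and has_three and has_polya
    is_chimeric = any(h.location == "internal" for h in hits)

    insert_start = five_hit.end if five_hit is not None else 0
    insert_end = tail.tail_start if tail is not None else region_end
    insert_end = max(insert_end, insert_start)

    return ReadClassification(
        read_id=read.read_id,
        has_five_prime=has_five,
        has_three_prime=has_three,
        has_polya=has_polya,
        is_full_length=is_fl,
        is_chimeric=is_chimeric,
        is_flnc=is_fl and not is_chimeric,
        trimmed_insert=seq[insert_start:insert_end],
        sample_label=read.sample_label,
        tail_length=tail.tail_length if tail is not None else None,
    )


@dataclass
class ClassificationSummary:
    """Per-sample and total read counts in the style of an Iso-Seq run report.

    Invariants: fl + nfl = reads_of_insert and flnc + chimeric = fl, per
    sample and in total.
    """

    per_sample: pd.DataFrame  # index: sample label; columns: SUMMARY_COLUMNS
    mean_flnc_length: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.per_sample
        for col in SUMMARY_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"summary missing column {col}")
        if not (df["fl_reads"] + df["nfl_reads"]).equals(df["reads_of_insert"]):
            raise ValueError("fl + nfl != reads_of_insert")
        if not (df["flnc_reads"] + df["chimeric_reads"]).equals(df["fl_reads"]):
            raise ValueError("flnc + chimeric != fl")
        for col in ("five_prime_reads", "three_prime_reads", "polya_reads"):
            if (df[col] > df["reads_of_insert"]).any():
                raise ValueError(f"{col} exceeds reads_of_insert")

    @property
    def totals(self) -> pd.Series:
        return self.per_sample[SUMMARY_COLUMNS].sum()

    def percent_of_total(self, column: str) -> float:
        """Percentage of reads of insert falling in ``column`` (2 decimals)."""
        totals = self.totals
        return percent(totals[column], totals["reads_of_insert"])

    @property
    def fl_percent(self) -> float:
        return self.percent_of_total("fl_reads")

    @property
    def nfl_percent(self) -> float:
        return self.percent_of_total("nfl_reads")

    @property
    def flnc_percent(self) -> float:
        return self.percent_of_total("flnc_reads")

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, int],
        sample: str = "Total",
        mean_flnc_length: float | None = None,
    ) -> "ClassificationSummary":
        """Build a single-row summary from counts, deriving what is implied.

        ``fl_reads`` may be omitted when ``flnc_reads`` and
        ``chimeric_reads`` are given (conservation: fl = flnc + chimeric);
        ``nfl_reads`` may be omitted when ``reads_of_insert`` is given.
        """
        c = dict(counts)
        if "fl_reads" not in c and {"flnc_reads", "chimeric_reads"} <= c.keys():
            c["fl_reads"] = c["flnc_reads"] + c["chimeric_reads"]
        if "nfl_reads" not in c and {"reads_of_insert", "fl_reads"} <= c.keys():
            c["nfl_reads"] = c["reads_of_insert"] - c["fl_reads"]
        for col in ("five_prime_reads", "three_prime_reads", "polya_reads"):
            c.setdefault(col, 0)
        missing = [col for col in SUMMARY_COLUMNS if col not in c]
        if missing:
            raise ValueError(f"cannot derive counts for: {', '.join(missing)}")
        df = pd.DataFrame([{col: c[col] for col in SUMMARY_COLUMNS}], index=[sample])
        return cls(per_sample=df, mean_flnc_length=mean_flnc_length)

    def to_frame(self) -> pd.DataFrame:
        """Per-sample table with a Total row and mean FLNC insert length."""
        df = self.per_sample.copy()
        df.loc["Total"] = self.totals
        df["mean_flnc_length"] = np.nan
        if self.mean_flnc_length is not None:
            df.loc["Total", "mean_flnc_length"] = round_half_up(
                self.mean_flnc_length, 2
            )
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")


def summarize_classification(
    classifications: Sequence[ReadClassification],
    sample_labels: Sequence[str] | None = None,
) -> ClassificationSummary:
    """Tabulate per-sample and total counts from read classifications.

    An empty input yields an all-zero summary with the mean FLNC length
    flagged as undefined (None).
    """
    labels = list(sample_labels) if sample_labels is not None else sorted(
        {c.sample_label for c in classifications}
    )
    if not labels:
        labels = [""]
    rows = {}
    for label in labels:
        group = [c for c in classifications if c.sample_label == label]
        rows[label] = {
            "reads_of_insert": len(group),
            "five_prime_reads": sum(c.has_five_prime for c in group),
            "three_prime_reads": sum(c.has_three_prime for c in group),
            "polya_reads": sum(c.has_polya for c in group),
            "nfl_reads": sum(not c.is_full_length for c in group),
            "fl_reads": sum(c.is_full_length for c in group),
            "flnc_reads": sum(c.is_flnc for c in group),
            "chimeric_reads": sum(c.is_full_length and c.is_chimeric for c in group),
        }
    flnc_lengths = [len(c.trimmed_insert) for c in classifications if c.is_flnc]
    mean_len = float(np.mean(flnc_lengths)) if flnc_lengths else None
    df = pd.DataFrame.from_dict(rows, orient="index")[SUMMARY_COLUMNS]
    return ClassificationSummary(per_sample=df, mean_flnc_length=mean_len)


def read_fastx(path: str | Path, sample_label: str = "") -> list[ReadOfInsert]:
    """Read FASTA or FASTQ reads of insert (format sniffed from the file)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    return [
        ReadOfInsert(rec.id, str(rec.seq).upper(), sample_label)
        for rec in SeqIO.parse(str(path), fmt)
    ]


def read_primer_config(path: str | Path) -> PrimerConfig:
    """Primer config from a plain ``key = value`` file.

    Keys: five_prime_primer, three_prime_primer, max_mismatch_fraction.
    """
    values: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
    return PrimerConfig(
        five_prime_primer=values["five_prime_primer"],
        three_prime_primer=values["three_prime_primer"],
        max_mismatch_fraction=float(values.get("max_mismatch_fraction", "0.1")),
    )
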