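"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the AS oracle matches
interval templates against per-base exon occupancy instead of walking site
chains; the collapse oracle enumerates all pairs and takes BFS components
instead of grouped union-find; the KS oracle sweeps both ECDFs pointwise.
"""

from __future__ import annotations

from collections import deque

from pegsplice.annotation import AlignedTranscript, TranscriptModel


# ---------------------------------------------------------------------------
# AS event template matching
# ---------------------------------------------------------------------------


def _sites(t: TranscriptModel) -> dict[int, str]:
    out = {}
    for a, b in t.introns:
        if t.strand == "+":
            out[a], out[b] = "donor", "acceptor"
        else:
            out[a], out[b] = "acceptor", "donor"
    return out


def _scoped(t: TranscriptModel, left: int, right: int) -> dict[int, str]:
    out = {}
    for a, b in t.introns:
        if left <= a and b <= right:
            if t.strand == "+":
                out[a], out[b] = "donor", "acceptor"
            else:
                out[a], out[b] = "acceptor", "donor"
    return out


def _all_exonic(t: TranscriptModel, start: int, end: int) -> bool:
    exonic = set()
    for e in t.exons:
        exonic.update(range(max(e.start, start), min(e.end, end)))
    return exonic == set(range(start, end))


def _all_intronic(t: TranscriptModel, start: int, end: int) -> bool:
    intronic = set()
    for a, b in t.introns:
        intronic.update(range(max(a, start), min(b, end)))
    return intronic == set(range(start, end))


def oracle_pairwise_events(
    t1: TranscriptModel, t2: TranscriptModel
) -> list[tuple[str, int, int]]:
    """(event_type, flank_left, flank_right) tuples by brute-force matching."""
    left = max(t1.start, t2.start)
    right = min(t1.end, t2.end)
    if left >= right:
        return []
    s1, s2 = _scoped(t1, left, right), _scoped(t2, left, right)
    shared = sorted(
        p for p in set(s1) & set(s2) if s1[p] == s2[p]
    )
    boundaries = [left] + shared + [right]
    events = []
    for lo, hi in zip(boundaries, boundaries[1:]):
        r1 = {p: k for p, k in s1.items() if lo < p < hi and s2.get(p) != k}
        r2 = {p: k for p, k in s2.items() if lo < p < hi and s1.get(p) != k}
        if not r1 and not r2:
            continue
        straddles = any(
            a < hi and lo < b and (a < left or b > right)
            for t in (t1, t2)
            for a, b in t.introns
        )
        if straddles:
            continue
        events.append((_match_templates(t1, t2, r1, r2), lo, hi))
    return sorted(events)


def _is_one_intron(t: TranscriptModel, run: dict[int, str]) -> tuple | None:
    if len(run) != 2:
        return None
    for a, b in t.introns:
        if set(run) == {a, b}:
            return (a, b)
    return None


def _is_one_exon(t: TranscriptModel, run: dict[int, str]) -> tuple | None:
    if len(run) != 2:
        return None
    for e in t.exons:
        if set(run) == {e.start, e.end}:
            return (e.start, e.end)
    return None


def _match_templates(t1, t2, r1: dict[int, str], r2: dict[int, str]) -> str:
    for inner_t, inner_r, other_t, other_r in (
        (t1, r1, t2, r2),
        (t2, r2, t1, r1),
    ):
        if other_r:
            continue
        intron = _is_one_intron(inner_t, inner_r)
        if intron is not None and _all_exonic(other_t, intron[0], intron[1]):
            return "IR"
        exon = _is_one_exon(inner_t, inner_r)
        if exon is not None and _all_intronic(other_t, exon[0], exon[1]):
            return "ES"
    if len(r1) == len(r2) == 1:
        k1, k2 = next(iter(r1.values())), next(iter(r2.values()))
        if k1 == k2 == "acceptor":
            return "AA"
        if k1 == k2 == "donor":
            return "AD"
    e1, e2 = _is_one_exon(t1, r1), _is_one_exon(t2, r2)
    if e1 is not None and e2 is not None and (e1[1] <= e2[0] or e2[1] <= e1[0]):
        return "MX"
    return "other"


# ---------------------------------------------------------------------------
# Collapse
# ---------------------------------------------------------------------------


def _introns_of(a: AlignedTranscript) -> tuple:
    exons = a.model.exons
    return tuple((x.end, y.start) for x, y in zip(exons, exons[1:]))


def _edge(
    a: AlignedTranscript,
    b: AlignedTranscript,
    tol5: int,
    tol3: int,
    se_overlap: float,
) -> bool:
    ma, mb = a.model, b.model
    if ma.chrom != mb.chrom or ma.strand != mb.strand:
        return False
    if _introns_of(a) != _introns_of(b):
        return False
    if not _introns_of(a):
        ov = min(ma.end, mb.end) - max(ma.start, mb.start)
        if ov <= 0:
            return False
        frac = min(ov / (ma.end - ma.start), ov / (mb.end - mb.start))
        return frac >= se_overlap
    if ma.strand == "+":
        d5, d3 = abs(ma.start - mb.start), abs(ma.end - mb.end)
    else:
        d5, d3 = abs(ma.end - mb.end), abs(ma.start - mb.start)
    return d5 <= tol5 and d3 <= tol3


def oracle_collapse(
    alignments,
    min_coverage: float = 0.8,
    min_identity: float = 0.7,
    tol5: int = 1000,
    tol3: int = 100,
    se_overlap: float = 0.5,
) -> list[tuple]:
    """Sorted (chrom, strand, introns, start, end, support) of merged isoforms."""
    surv = [
        a for a in alignments if a.coverage >= min_coverage and a.identity >= min_identity
    ]
    n = len(surv)
    adj = {i: [] for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if _edge(surv[i], surv[j], tol5, tol3, se_overlap):
                adj[i].append(j)
                adj[j].append(i)
    seen: set[int] = set()
    out = []
    for i in range(n):
        if i in seen:
            continue
        queue = deque([i])
        comp = []
        seen.add(i)
        while queue:
            k = queue.popleft()
            comp.append(k)
            for nb in adj[k]:
                if nb not in seen:
                    seen.add(nb)
                    queue.append(nb)
        members = [surv[k] for k in comp]
        out.append(
            (
                members[0].model.chrom,
                members[0].model.strand,
                _introns_of(members[0]),
                min(m.model.start for m in members),
                max(m.model.end for m in members),
                len(members),
            )
        )
    return sorted(out)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------


def oracle_ks_d(a, b) -> float:
    """sup |ECDF_a - ECDF_b| by a double loop over all sample points."""
    best = 0.0
    for x in list(a) + list(b):
        fa = sum(1 for v in a if v <= x) / len(a)
        fb = sum(1 for v in b if v <= x) / len(b)
        best = max(best, abs(fa - fb))
    return best
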