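"""Core split-read junction inference.

Two aligned parts of one read that fall in genomic order within one gene
at an admissible distance form a *matched pair* — the unit of junction
evidence.  Pairs support each other when both boundaries agree within a
coordinate buffer (default 5 nt), absorbing alignment wobble caused by
repeated sequence around the splice site.  Clustering is anchor-based and
greedy: the most frequent exact junction among unassigned pairs becomes
the candidate's coordinates and absorbs every unassigned pair within the
buffer.  Reads whose short side multi-mapped (and therefore produced no
matched pair) can still contribute support through their uniquely-mapped
longer side (*rescue*).  A candidate becomes a call when its distinct
supporting reads (members + rescues) reach the SUPP threshold.
"""

from __future__ import annotations

import heapq
from bisect import bisect_left, bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .align import SUPPRESSED_MULTI, UNIQUE_HITS, AlignmentHit, AlignResult
from .seqio import GeneModel, GenomeSequence

__all__ = [
    "MatchedPair",
    "JunctionCandidate",
    "JunctionCall",
    "GeneIndex",
    "form_matched_pairs",
    "cluster_support",
    "rescue_long_sides",
    "call_junctions",
    "compare_runs",
    "DEFAULT_MIN_D",
    "DEFAULT_MAX_D",
    "DEFAULT_SUPP",
    "DEFAULT_BUFFER",
]

DEFAULT_MIN_D = 2
DEFAULT_MAX_D = 50_000
DEFAULT_SUPP = 2
DEFAULT_BUFFER = 5


@dataclass(frozen=True)
class MatchedPair:
    """Two complementary parts of one read in genomic order within a gene.

    left_interval/right_interval are 0-based half-open and genomically
    ordered; on the minus strand the read's left side is the genomically
    *right* interval.
    """

    read_id: str
    split_position: int
    chrom: str
    strand: str
    left_interval: tuple[int, int]
    right_interval: tuple[int, int]
    gene_name: str

    @property
    def left_end(self) -> int:
        return self.left_interval[1]

    @property
    def right_start(self) -> int:
        return self.right_interval[0]

    @property
    def gap(self) -> int:
        return self.right_start - self.left_end


@dataclass
class JunctionCandidate:
    chrom: str
    strand: str
    left_end: int
    right_start: int
    members: list[MatchedPair] = field(default_factory=list)
    rescue_support: int = 0
    rescue_reads: set = field(default_factory=set)

    @property
    def splice_length(self) -> int:
        return self.right_start - self.left_end

    @property
    def member_reads(self) -> set[str]:
        return {m.read_id for m in self.members}

    @property
    def support(self) -> int:
        """Distinct supporting reads: members counted once per read, plus
        rescued reads (disjoint from members by construction)."""
        return len(self.member_reads) + self.rescue_support


@dataclass(frozen=True)
class JunctionCall:
    chrom: str
    strand: str
    left_end: int
    right_start: int
    splice_length: int
    support: int
    gene_name: str
    excised_sequence: str
    novelty: str  # 'known' | 'novel'

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.chrom, self.left_end, self.right_start)


class GeneIndex:
    """Per-chromosome gene spans (union of transcript spans per gene_name),
    sorted for bisect lookup.  A pair is in-gene when both intervals fall
    inside one gene's span; with overlapping genes the smallest containing
    span wins, ties broken lexicographically by gene name."""

    def __init__(self, genes: Sequence[GeneModel]):
        spans: dict[tuple[str, str], tuple[int, int]] = {}
        for g in genes:
            key = (g.chrom, g.gene_name)
            if key in spans:
                s, e = spans[key]
                spans[key] = (min(s, g.tx_start), max(e, g.tx_end))
            else:
                spans[key] = (g.tx_start, g.tx_end)
        self._by_chrom: dict[str, list[tuple[int, int, str]]] = defaultdict(list)
        for (chrom, name), (s, e) in spans.items():
            self._by_chrom[chrom].append((s, e, name))
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort()
        self._starts = {c: [s for s, _, _ in v] for c, v in self._by_chrom.items()}

    def assign(self, chrom: str, start: int, end: int) -> Optional[str]:
        """Most specific gene whose span contains [start, end), or None."""
        spans = self._by_chrom.get(chrom)
        if not spans:
            return None
        idx = bisect_right(self._starts[chrom], start)
        best: Optional[tuple[int, str]] = None
        for s, e, name in spans[:idx]:
            if s <= start and end <= e:
                size = e - s
                if best is None or (size, name) < best:
                    best = (size, name)
        return best[1] if best else None


def form_matched_pairs(
    part_results: dict[tuple[str, int], dict[str, AlignResult]],
    genes: GeneIndex | Sequence[GeneModel],
    min_d: int = DEFAULT_MIN_D,
    max_d: int = DEFAULT_MAX_D,
) -> list[MatchedPair]:
    """Build matched pairs from per-(read, split position) part alignments.

    ``part_results`` maps (read_id, p) -> {'L': AlignResult, 'R': AlignResult}.
    Every combination of a reported left-part hit and right-part hit on the
    same chromosome and strand, in genomic order with gap in [min_d, max_d]
    and both intervals inside one gene's span, yields one pair.  On the
    minus strand the read's left part lies genomically right of its right
    part, so the roles flip when ordering the intervals.
    """
    if not isinstance(genes, GeneIndex):
        genes = GeneIndex(genes)
    pairs: list[MatchedPair] = []
    for (read_id, p), sides in part_results.items():
        left_res = sides.get("L")
        right_res = sides.get("R")
        if left_res is None or right_res is None:
            continue
        if left_res.status != UNIQUE_HITS or right_res.status != UNIQUE_HITS:
            continue
        for hl in left_res.hits:
            for hr in right_res.hits:
                if hl.chrom != hr.chrom or hl.strand != hr.strand:
                    continue
                if hl.strand == "+":
                    g_left, g_right = (hl.start, hl.end), (hr.start, hr.end)
                else:
                    # read layout is mirrored on the minus strand
                    g_left, g_right = (hr.start, hr.end), (hl.start, hl.end)
                gap = g_right[0] - g_left[1]
                if gap < min_d or gap > max_d:
                    continue
                gene = genes.assign(hl.chrom, g_left[0], g_right[1])
                if gene is None:
                    continue
                pairs.append(
                    MatchedPair(read_id, p, hl.chrom, hl.strand, g_left, g_right, gene)
                )
    return pairs


def cluster_support(pairs: Iterable[MatchedPair], buffer: int = DEFAULT_BUFFER) -> list[JunctionCandidate]:
    """Greedy anchor-based clustering of matched pairs.

    Within each (chrom, strand), pairs are grouped by exact
    (left_end, right_start) junction; the most frequent exact junction
    (ties -> smallest coordinates) anchors a candidate and absorbs every
    yet-unassigned junction whose boundaries both lie within ``buffer``
    of the anchor (boundary-inclusive).  Anchoring, rather than
    transitive chaining, keeps junctions ~2*buffer apart separate while
    still absorbing alignment wobble.

    Implemented as a sorted sweep: exact junctions are sorted by
    (left_end, right_start) and each anchor inspects only the window of
    junctions with left_end within buffer (bisect on the sorted keys).
    """
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    groups: dict[tuple[str, str], dict[tuple[int, int], list[MatchedPair]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for pr in pairs:
        groups[(pr.chrom, pr.strand)][(pr.left_end, pr.right_start)].append(pr)

    candidates: list[JunctionCandidate] = []
    for (chrom, strand), exact in sorted(groups.items()):
        keys = sorted(exact)
        lefts = [k[0] for k in keys]
        # max-heap with lazy deletion; ties resolved toward smaller coordinates
        heap = [(-len(exact[k]), k) for k in keys]
        heapq.heapify(heap)
        assigned: set[tuple[int, int]] = set()
        while heap:
            negn, anchor = heapq.heappop(heap)
            if anchor in assigned:
                continue
            assigned.add(anchor)
            cand = JunctionCandidate(chrom, strand, anchor[0], anchor[1], list(exact[anchor]))
            lo = bisect_left(lefts, anchor[0] - buffer)
            hi = bisect_right(lefts, anchor[0] + buffer)
            for k in keys[lo:hi]:
                if k in assigned:
                    continue
                if abs(k[1] - anchor[1]) <= buffer:
                    assigned.add(k)
                    cand.members.extend(exact[k])
            candidates.append(cand)
    candidates.sort(key=lambda c: (c.chrom, c.left_end, c.right_start, c.strand))
    return candidates


def cluster_support_bruteforce(
    pairs: Iterable[MatchedPair], buffer: int = DEFAULT_BUFFER
) -> list[JunctionCandidate]:
    """O(n^2) reference implementation of the same greedy clustering, built
    from the full pairwise support matrix; used as an oracle in tests."""
    pairs = list(pairs)
    remaining = set(range(len(pairs)))
    candidates: list[JunctionCandidate] = []
    while remaining:
        counts: Counter = Counter(
            (pairs[i].chrom, pairs[i].strand, pairs[i].left_end, pairs[i].right_start)
            for i in remaining
        )
        # most frequent exact junction; ties -> smallest key
        anchor = min(counts, key=lambda k: (-counts[k], k))
        chrom, strand, le, rs = anchor
        cand = JunctionCandidate(chrom, strand, le, rs)
        for i in sorted(remaining):
            pr = pairs[i]
            if (
                pr.chrom == chrom
                and pr.strand == strand
                and abs(pr.left_end - le) <= buffer
                and abs(pr.right_start - rs) <= buffer
            ):
                cand.members.append(pr)
                remaining.discard(i)
        candidates.append(cand)
    candidates.sort(key=lambda c: (c.chrom, c.left_end, c.right_start, c.strand))
    return candidates


@dataclass(frozen=True)
class RescueHit:
    """A uniquely-informative long-side alignment of a read that produced no
    matched pair (its short side was suppressed for multi-mapping)."""

    read_id: str
    side: str  # read side of the long part: 'L' or 'R'
    hit: AlignmentHit


def rescue_long_sides(
    rescue_hits: Iterable[RescueHit],
    candidates: list[JunctionCandidate],
    buffer: int = DEFAULT_BUFFER,
) -> list[JunctionCandidate]:
    """Credit long-side support to existing candidates.

    For each read with no matched pairs, the long side's inner boundary
    (its 3' end for a genomically-left part, its 5' start for a
    genomically-right part) is compared against candidate boundaries on
    the same chromosome and strand; if it lies within ``buffer`` of the
    matching boundary the nearest candidate (ties -> leftmost) gains +1
    rescue support.  Each read contributes at most once.  Candidates are
    mutated in place and returned.
    """
    by_cs: dict[tuple[str, str], list[JunctionCandidate]] = defaultdict(list)
    for c in candidates:
        by_cs[(c.chrom, c.strand)].append(c)
    for key in by_cs:
        by_cs[key].sort(key=lambda c: (c.left_end, c.right_start))

    per_read: dict[str, list[RescueHit]] = defaultdict(list)
    for rh in rescue_hits:
        per_read[rh.read_id].append(rh)

    for read_id in sorted(per_read):
        best: Optional[tuple[int, int, int, JunctionCandidate]] = None
        for rh in per_read[read_id]:
            cands = by_cs.get((rh.hit.chrom, rh.hit.strand))
            if not cands:
                continue
            # genomically-left part <=> read side matches strand orientation
            is_genomic_left = (rh.side == "L") == (rh.hit.strand == "+")
            for cand in cands:
                if is_genomic_left:
                    dist = abs(rh.hit.end - cand.left_end)
                else:
                    dist = abs(rh.hit.start - cand.right_start)
                if dist <= buffer:
                    rank = (dist, cand.left_end, cand.right_start)
                    if best is None or rank < best[:3]:
                        best = (*rank, cand)
        if best is not None:
            cand = best[3]
            if read_id not in cand.member_reads and read_id not in cand.rescue_reads:
                cand.rescue_reads.add(read_id)
                cand.rescue_support += 1
    return candidates


def call_junctions(
    candidates: Iterable[JunctionCandidate],
    genome: Sequence[GenomeSequence],
    supp: int = DEFAULT_SUPP,
    annotation: Optional[Sequence[GeneModel]] = None,
    known_tolerance: int = 0,
) -> list[JunctionCall]:
    """Promote sufficiently-supported candidates to junction calls.

    Support counts distinct reads (members once per read, plus rescues).
    The excised sequence is the genome slice [left_end, right_start);
    novelty is 'known' when the junction coincides with an annotated
    intron within ``known_tolerance`` nt on both boundaries.
    """
    if supp < 1:
        raise ValueError("supp must be >= 1")
    by_name = {g.chrom_name: g.bases for g in genome}
    from .evaluate import junction_novelty  # late import: module cycle

    calls: list[JunctionCall] = []
    for cand in candidates:
        if cand.support < supp:
            continue
        bases = by_name.get(cand.chrom)
        if bases is None:
            raise ValueError(f"candidate on unknown chromosome {cand.chrom!r}")
        excised = bases[cand.left_end : cand.right_start]
        gene = Counter(m.gene_name for m in cand.members).most_common(1)[0][0]
        novelty = "novel"
        if annotation is not None:
            novelty = junction_novelty(
                cand.chrom, cand.left_end, cand.right_start, annotation, known_tolerance
            )
        calls.append(
            JunctionCall(
                chrom=cand.chrom,
                strand=cand.strand,
                left_end=cand.left_end,
                right_start=cand.right_start,
                splice_length=cand.splice_length,
                support=cand.support,
                gene_name=gene,
                excised_sequence=excised,
                novelty=novelty,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.left_end, c.right_start, c.strand))
    return calls


def compare_runs(
    calls_a: Sequence[JunctionCall],
    calls_b: Sequence[JunctionCall],
    buffer: int = DEFAULT_BUFFER,
) -> dict[str, list]:
    """Side-by-side comparison of two call sets from the same reference.

    A call in A is *common* when some call in B agrees on chromosome and
    on both boundaries within ``buffer``; matching is greedy nearest-first
    (total boundary offset), each call matched at most once.  Returns
    {'common': [(a, b), ...], 'unique_a': [...], 'unique_b': [...]} — an
    exhaustive, disjoint partition of both inputs.
    """
    edges = []
    for i, a in enumerate(calls_a):
        for j, b in enumerate(calls_b):
            if a.chrom != b.chrom:
                continue
            dl = abs(a.left_end - b.left_end)
            dr = abs(a.right_start - b.right_start)
            if dl <= buffer and dr <= buffer:
                edges.append((dl + dr, i, j))
    edges.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    common: list[tuple[JunctionCall, JunctionCall]] = []
    for _, i, j in edges:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        common.append((calls_a[i], calls_b[j]))
    return {
        "common": common,
        "unique_a": [a for i, a in enumerate(calls_a) if i not in used_a],
        "unique_b": [b for j, b in enumerate(calls_b) if j not in used_b],
    }
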