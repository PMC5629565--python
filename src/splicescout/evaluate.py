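"""Validation and accuracy metrics for junction call sets.

A detected junction is EST-validated when its left boundary lies within a
small buffer (default 5 bp) of some EST alignment end and its right
boundary within the buffer of some EST alignment start, on the same
chromosome.  Specificity is the EST-validated fraction of calls (reported
for all calls and for novel calls separately); sensitivity is the fraction
of annotated junctions recovered, restricted to genes that contributed at
least one detected known junction, optionally stratified by gene-level
RPKM (reads per kilobase of exonic model per million mapped reads).
A frequency-based two-group comparison flags junctions whose per-group
occurrence frequencies differ by more than a threshold (default 0.5).
"""

from __future__ import annotations

from bisect import bisect_left
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .seqio import EstInterval, GeneModel

__all__ = [
    "ValidationVerdict",
    "RpkmRecord",
    "GroupFrequencyRow",
    "EstBoundaryIndex",
    "validate_with_est",
    "classify_known_novel",
    "junction_novelty",
    "specificity",
    "sensitivity",
    "compute_rpkm",
    "rpkm_bin",
    "group_frequency_comparison",
    "RPKM_BIN_EDGES",
    "DEFAULT_EST_BUFFER",
    "DEFAULT_FREQ_THRESHOLD",
]

DEFAULT_EST_BUFFER = 5
DEFAULT_FREQ_THRESHOLD = 0.5
# bin 1: [0,5), 2: [5,10), 3: [10,50), 4: [50,100), 5: [100, inf)
RPKM_BIN_EDGES = (5.0, 10.0, 50.0, 100.0)


@dataclass(frozen=True)
class ValidationVerdict:
    call_key: tuple[str, int, int]
    est_validated: bool
    novelty: str


@dataclass(frozen=True)
class RpkmRecord:
    gene_name: str
    exonic_length: int
    read_count: int
    total_mapped: int
    rpkm: float
    bin: int


@dataclass(frozen=True)
class GroupFrequencyRow:
    key: tuple[str, int, int]
    freq_a: float
    freq_b: float

    @property
    def delta(self) -> float:
        return self.freq_a - self.freq_b


class EstBoundaryIndex:
    """Sorted per-chromosome EST end/start positions for buffered lookup."""

    def __init__(self, ests: Sequence[EstInterval]):
        ends: dict[str, list[int]] = defaultdict(list)
        starts: dict[str, list[int]] = defaultdict(list)
        for e in ests:
            ends[e.chrom].append(e.end)
            starts[e.chrom].append(e.start)
        self._ends = {c: sorted(v) for c, v in ends.items()}
        self._starts = {c: sorted(v) for c, v in starts.items()}

    @staticmethod
    def _near(sorted_vals: list[int], pos: int, buffer: int) -> bool:
        i = bisect_left(sorted_vals, pos - buffer)
        return i < len(sorted_vals) and sorted_vals[i] <= pos + buffer

    def validates(self, chrom: str, left_end: int, right_start: int, buffer: int) -> bool:
        ends = self._ends.get(chrom)
        starts = self._starts.get(chrom)
        if not ends or not starts:
            return False
        return self._near(ends, left_end, buffer) and self._near(starts, right_start, buffer)


def validate_with_est(
    call, ests: Sequence[EstInterval] | EstBoundaryIndex, buffer: int = DEFAULT_EST_BUFFER
) -> bool:
    """True iff some EST end lies within ``buffer`` of the call's left
    boundary and some (possibly different) EST start within ``buffer`` of
    its right boundary, on the call's chromosome."""
    idx = ests if isinstance(ests, EstBoundaryIndex) else EstBoundaryIndex(list(ests))
    return idx.validates(call.chrom, call.left_end, call.right_start, buffer)


def junction_novelty(
    chrom: str,
    left_end: int,
    right_start: int,
    genes: Sequence[GeneModel],
    tolerance: int = 0,
) -> str:
    """'known' when some transcript has consecutive exons whose intron
    matches (left_end, right_start) within ``tolerance`` nt on both
    boundaries; otherwise 'novel'."""
    for g in genes:
        if g.chrom != chrom:
            continue
        for le, rs in g.junctions():
            if abs(le - left_end) <= tolerance and abs(rs - right_start) <= tolerance:
                return "known"
    return "novel"


def classify_known_novel(call, genes: Sequence[GeneModel], tolerance: int = 0) -> str:
    return junction_novelty(call.chrom, call.left_end, call.right_start, genes, tolerance)


def specificity(
    calls: Sequence, ests: Sequence[EstInterval], buffer: int = DEFAULT_EST_BUFFER
) -> dict[str, Optional[float]]:
    """EST-validated fraction of all calls and of novel calls.

    A ratio with an empty denominator is reported as None, not 0.
    """
    idx = EstBoundaryIndex(list(ests))
    validated = [validate_with_est(c, idx, buffer) for c in calls]
    novel_mask = [c.novelty == "novel" for c in calls]
    out: dict[str, Optional[float]] = {"all": None, "novel": None}
    if calls:
        out["all"] = sum(validated) / len(calls)
    n_novel = sum(novel_mask)
    if n_novel:
        out["novel"] = sum(v for v, m in zip(validated, novel_mask) if m) / n_novel
    return out


def _gene_junction_sets(genes: Sequence[GeneModel]) -> dict[str, set[tuple[str, int, int]]]:
    """Union of annotated junctions over all isoforms, per gene_name."""
    sets: dict[str, set[tuple[str, int, int]]] = defaultdict(set)
    for g in genes:
        for le, rs in g.junctions():
            sets[g.gene_name].add((g.chrom, le, rs))
    return dict(sets)


def _isoform_counts(genes: Sequence[GeneModel]) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for g in genes:
        counts[g.gene_name] += 1
    return counts


def sensitivity(
    calls: Sequence,
    genes: Sequence[GeneModel],
    rpkm: Optional[Sequence[RpkmRecord]] = None,
    single_isoform_only: bool = False,
    tolerance: int = 0,
) -> dict:
    """Recovered fraction of annotated junctions of detected genes.

    The denominator is the number of annotated junctions (union over
    isoforms) of genes that contributed at least one detected known
    junction; the numerator is how many of those junctions were detected.
    Genes with zero detected known junctions are excluded entirely.  With
    ``single_isoform_only`` the computation is restricted to genes with
    exactly one transcript.  When ``rpkm`` records are supplied the same
    ratio is also reported per RPKM bin.

    Returns {'overall': float|None, 'n_detected': int, 'n_possible': int,
    'bins': {bin: {...}}}.
    """
    gene_juncs = _gene_junction_sets(genes)
    if single_isoform_only:
        iso = _isoform_counts(genes)
        gene_juncs = {g: j for g, j in gene_juncs.items() if iso[g] == 1}

    # a call is a detected known junction of a gene when it matches one of
    # the gene's annotated junctions within the tolerance (the stored
    # novelty label is not consulted: it may have been assigned under a
    # different tolerance)
    detected: dict[str, set[tuple[str, int, int]]] = defaultdict(set)
    for c in calls:
        for gname, juncs in gene_juncs.items():
            for chrom, le, rs in juncs:
                if (
                    chrom == c.chrom
                    and abs(le - c.left_end) <= tolerance
                    and abs(rs - c.right_start) <= tolerance
                ):
                    detected[gname].add((chrom, le, rs))

    def ratio(gene_names: Iterable[str]) -> tuple[Optional[float], int, int]:
        num = sum(len(detected[g]) for g in gene_names if g in detected)
        den = sum(len(gene_juncs[g]) for g in gene_names if g in detected)
        return (num / den if den else None), num, den

    overall, num, den = ratio(gene_juncs.keys())
    result = {"overall": overall, "n_detected": num, "n_possible": den, "bins": {}}
    if rpkm is not None:
        by_bin: dict[int, list[str]] = defaultdict(list)
        for rec in rpkm:
            if rec.gene_name in gene_juncs:
                by_bin[rec.bin].append(rec.gene_name)
        for b in range(1, 6):
            frac, bnum, bden = ratio(by_bin.get(b, []))
            result["bins"][b] = {"overall": frac, "n_detected": bnum, "n_possible": bden}
    return result


def rpkm_bin(value: float) -> int:
    """Half-open bins [0,5), [5,10), [10,50), [50,100), [100,inf)."""
    for i, edge in enumerate(RPKM_BIN_EDGES, start=1):
        if value < edge:
            return i
    return 5


def compute_rpkm(
    gene_models: Sequence[GeneModel],
    mapped_read_starts: Iterable[tuple[str, int]],
    total_mapped: int,
) -> RpkmRecord:
    """RPKM for one gene (all ``gene_models`` share a gene_name).

    A read counts toward the gene when its alignment start lies inside the
    gene's exonic union; rpkm = count * 1e9 / (exonic_length * total_mapped).
    """
    if total_mapped < 1:
        raise ValueError("total_mapped must be >= 1")
    names = {g.gene_name for g in gene_models}
    if len(names) != 1:
        raise ValueError(f"compute_rpkm expects one gene, got {sorted(names)}")
    # exonic union across isoforms
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for g in gene_models:
        for s, e in zip(g.exon_starts, g.exon_ends):
            by_chrom[g.chrom].append((s, e))
    union: dict[str, list[tuple[int, int]]] = {}
    exonic_length = 0
    for chrom, ivals in by_chrom.items():
        merged: list[tuple[int, int]] = []
        for s, e in sorted(ivals):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        union[chrom] = merged
        exonic_length += sum(e - s for s, e in merged)

    count = 0
    for chrom, start in mapped_read_starts:
        for s, e in union.get(chrom, ()):  # few exons per gene; linear scan
            if s <= start < e:
                count += 1
                break
    rpkm = count * 1e9 / (exonic_length * total_mapped)
    return RpkmRecord(next(iter(names)), exonic_length, count, total_mapped, rpkm, rpkm_bin(rpkm))


def compute_rpkm_table(
    genes: Sequence[GeneModel],
    mapped_read_starts: Sequence[tuple[str, int]],
    total_mapped: int,
) -> list[RpkmRecord]:
    """RPKM for every gene_name present in ``genes``."""
    by_gene: dict[str, list[GeneModel]] = defaultdict(list)
    for g in genes:
        by_gene[g.gene_name].append(g)
    return [
        compute_rpkm(models, mapped_read_starts, total_mapped)
        for _, models in sorted(by_gene.items())
    ]


def group_frequency_comparison(
    per_sample_calls: Mapping[str, Sequence],
    labels: Mapping[str, str],
    threshold: float = DEFAULT_FREQ_THRESHOLD,
) -> list[GroupFrequencyRow]:
    """Frequency-difference screen between two sample groups.

    Junctions are unified across samples by exact (chrom, left, right).
    For each junction, freq in a group = fraction of that group's samples
    containing it; rows with |freq_a − freq_b| strictly greater than
    ``threshold`` are returned, sorted by |delta| descending then key.
    """
    groups: dict[str, list[str]] = {"a": [], "b": []}
    for sample, lab in labels.items():
        if lab not in groups:
            raise ValueError(f"label {lab!r} for sample {sample!r}: expected 'a' or 'b'")
        groups[lab].append(sample)
    if not groups["a"] or not groups["b"]:
        raise ValueError("both groups must be non-empty")

    presence: dict[tuple[str, int, int], set[str]] = defaultdict(set)
    for sample, calls in per_sample_calls.items():
        for c in calls:
            presence[(c.chrom, c.left_end, c.right_start)].add(sample)

    rows = []
    for key, samples in presence.items():
        fa = sum(1 for s in groups["a"] if s in samples) / len(groups["a"])
        fb = sum(1 for s in groups["b"] if s in samples) / len(groups["b"])
        if abs(fa - fb) > threshold:
            rows.append(GroupFrequencyRow(key, fa, fb))
    rows.sort(key=lambda r: (-abs(r.delta), r.key))
    return rows
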