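"""Exact-match alignment of reads and read parts against a reference.

The built-in engine mirrors the split-phase aligner settings of the
pipeline: no mismatches, all full-length exact matches on both strands
counted, and all alignments suppressed when a query matches more than
``max_alignments`` genomic locations.  A mismatch-tolerant initial phase
can be delegated to any external short-read aligner through
:class:`ExternalAligner`, which consumes FASTQ and parses the SAM it
produces (mandatory fields only).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence, Union

import pysam

from .seqio import GenomeSequence, ReadRecord, revcomp
from .splitting import SplitPart

__all__ = [
    "AlignmentHit",
    "AlignResult",
    "SeedIndex",
    "build_index",
    "align_exact",
    "initial_align",
    "ExternalAligner",
    "UNMAPPED",
    "UNIQUE_HITS",
    "SUPPRESSED_MULTI",
]

UNIQUE_HITS = "unique_hits"
SUPPRESSED_MULTI = "suppressed_multi"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class AlignmentHit:
    """A full-length exact match; coordinates are 0-based half-open on the
    forward strand of ``chrom`` regardless of hit strand."""

    query_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass(frozen=True)
class AlignResult:
    query_id: str
    status: str
    hits: tuple[AlignmentHit, ...] = ()

    @property
    def mapped(self) -> bool:
        return self.status == UNIQUE_HITS


class SeedIndex:
    """k-mer location index over the forward strand of every chromosome.

    Full-length exact lookup: candidate starts come from the query's first
    k-mer; each candidate is verified by string comparison.  Reverse-strand
    matches are found by searching the reverse complement of the query on
    the forward strand.  Queries shorter than k fall back to a direct scan.
    """

    def __init__(self, genome: Sequence[GenomeSequence], k: int):
        if k < 1:
            raise ValueError("seed length k must be >= 1")
        self.k = k
        self.chroms: dict[str, str] = {g.chrom_name: g.bases for g in genome}
        self._index: dict[str, list[tuple[str, int]]] = {}
        for g in genome:
            bases = g.bases
            for i in range(len(bases) - k + 1):
                kmer = bases[i : i + k]
                if "N" in kmer:
                    continue
                self._index.setdefault(kmer, []).append((g.chrom_name, i))

    def lookup_forward(self, query: str) -> list[tuple[str, int]]:
        """All forward-orientation occurrences of ``query`` (chrom, start)."""
        q = len(query)
        if q < self.k:
            return self._scan(query)
        out = []
        for chrom, start in self._index.get(query[: self.k], ()):  # verified candidates
            if self.chroms[chrom][start : start + q] == query:
                out.append((chrom, start))
        return out

    def _scan(self, query: str) -> list[tuple[str, int]]:
        out = []
        for chrom, bases in self.chroms.items():
            pos = bases.find(query)
            while pos != -1:
                out.append((chrom, pos))
                pos = bases.find(query, pos + 1)
        return out


def build_index(genome: Sequence[GenomeSequence], k: int) -> SeedIndex:
    """Build the exact-location index; k must not exceed the shortest query
    that will be searched (the pipeline enforces k <= min_split_size)."""
    return SeedIndex(genome, k)


def align_exact(
    query: Union[SplitPart, ReadRecord, tuple[str, str]],
    index: SeedIndex,
    max_alignments: int = 2,
) -> AlignResult:
    """All full-length exact matches of ``query`` on both strands.

    More than ``max_alignments`` total matches suppresses the query
    entirely (no hits reported); zero matches is unmapped.  Queries
    containing N are unmapped by convention.
    """
    if isinstance(query, tuple):
        qid, bases = query
    elif isinstance(query, SplitPart):
        from .splitting import part_id

        qid, bases = part_id(query), query.bases
    else:
        qid, bases = query.read_id, query.bases
    if "N" in bases or not bases:
        return AlignResult(qid, UNMAPPED)
    hits = [
        AlignmentHit(qid, chrom, "+", start, start + len(bases))
        for chrom, start in index.lookup_forward(bases)
    ]
    rc = revcomp(bases)
    hits += [
        AlignmentHit(qid, chrom, "-", start, start + len(bases))
        for chrom, start in index.lookup_forward(rc)
    ]
    if not hits:
        return AlignResult(qid, UNMAPPED)
    if len(hits) > max_alignments:
        return AlignResult(qid, SUPPRESSED_MULTI)
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return AlignResult(qid, UNIQUE_HITS, tuple(hits))


def initial_align(
    reads: Iterable[ReadRecord],
    index: Optional[SeedIndex] = None,
    engine: str = "internal",
    external: Optional["ExternalAligner"] = None,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Partition reads into (mapped, unmapped); only the unmapped partition
    proceeds to splitting.

    With the internal engine a read is mapped iff it has at least one
    full-length exact genomic match on either strand.  The external engine
    delegates to a mismatch-tolerant short-read aligner.
    """
    if engine == "internal":
        if index is None:
            raise ValueError("internal engine requires a SeedIndex")
        mapped: list[ReadRecord] = []
        unmapped: list[ReadRecord] = []
        for read in reads:
            if "N" in read.bases:
                unmapped.append(read)
                continue
            if index.lookup_forward(read.bases) or index.lookup_forward(revcomp(read.bases)):
                mapped.append(read)
            else:
                unmapped.append(read)
        return mapped, unmapped
    if engine == "external":
        if external is None:
            raise EnvironmentError(
                "external aligner adapter not configured; fall back to --engine internal"
            )
        return external.partition(reads)
    raise ValueError(f"unknown engine {engine!r}")


def initial_align_hits(
    reads: Iterable[ReadRecord], index: SeedIndex
) -> tuple[dict[str, AlignmentHit], list[ReadRecord]]:
    """Like :func:`initial_align` but also returns one representative hit per
    mapped read (first in (chrom, start) order) for expression counting."""
    hits: dict[str, AlignmentHit] = {}
    unmapped: list[ReadRecord] = []
    for read in reads:
        locs: list[tuple[str, int, str]] = []
        if "N" not in read.bases:
            locs = [(c, s, "+") for c, s in index.lookup_forward(read.bases)]
            locs += [(c, s, "-") for c, s in index.lookup_forward(revcomp(read.bases))]
        if not locs:
            unmapped.append(read)
            continue
        chrom, start, strand = min(locs)
        hits[read.read_id] = AlignmentHit(read.read_id, chrom, strand, start, start + len(read))
    return hits, unmapped


class ExternalAligner:
    """Adapter around a SAM-producing external short-read aligner.

    ``command`` is a template with ``{fastq}`` and ``{sam}`` placeholders,
    e.g. ``"bowtie -n 3 -e 112 -S idx {fastq} {sam}"``.  Only SAM mandatory
    fields are consumed.
    """

    def __init__(self, command: str, workdir=None):
        self.command = command
        self.workdir = workdir
        tool = command.split()[0]
        if shutil.which(tool) is None:
            raise EnvironmentError(
                f"external aligner {tool!r} not found on PATH; "
                "fall back to the internal exact-match engine (--engine internal)"
            )

    def partition(self, reads: Iterable[ReadRecord]) -> tuple[list[ReadRecord], list[ReadRecord]]:
        import tempfile
        from pathlib import Path

        from .seqio import write_fastq

        reads = list(reads)
        with tempfile.TemporaryDirectory(dir=self.workdir) as tmp:
            fastq = Path(tmp) / "reads.fastq"
            sam = Path(tmp) / "out.sam"
            write_fastq(reads, fastq)
            cmd = self.command.format(fastq=fastq, sam=sam)
            subprocess.run(cmd, shell=True, check=True)
            mapped_ids = parse_sam_mapped_ids(sam)
        mapped = [r for r in reads if r.read_id in mapped_ids]
        unmapped = [r for r in reads if r.read_id not in mapped_ids]
        return mapped, unmapped


def parse_sam_mapped_ids(sam_path) -> set[str]:
    """Query names with at least one mapped alignment in a SAM file."""
    mapped: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
        for rec in fh:
            if not rec.is_unmapped:
                mapped.add(rec.query_name)
    return mapped


def naive_exact_hits(genome: Sequence[GenomeSequence], query: str) -> set[tuple[str, str, int]]:
    """Brute-force both-strand scan; independent oracle for align_exact.

    Returns {(chrom, strand, start)} of every full-length exact match.
    """
    out: set[tuple[str, str, int]] = set()
    rc = revcomp(query)
    for g in genome:
        for strand, pattern in (("+", query), ("-", rc)):
            pos = g.bases.find(pattern)
            while pos != -1:
                out.add((g.chrom_name, strand, pos))
                pos = g.bases.find(pattern, pos + 1)
    return out
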