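"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 0-based half-open internally.  The single
conversion to the UCSC-browser 1-based inclusive convention happens in
:func:`write_junction_table`; refFlat and BED are natively 0-based
half-open, GTF (the UCSC table-browser EST export format) is 1-based
inclusive and is normalized on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "ReadRecord",
    "GeneModel",
    "EstInterval",
    "FormatError",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_fastq",
    "read_refflat",
    "read_est_intervals",
    "write_junction_table",
    "write_spliced_fasta",
    "revcomp",
]

JUNCTION_TABLE_COLUMNS = (
    "chrom",
    "left_boundary",
    "right_boundary",
    "splice_length",
    "support",
    "novelty",
    "gene_name",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


class FormatError(ValueError):
    """Malformed record in an input file."""


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize_bases(raw: str) -> str:
    """Uppercase and map every non-ACGT character (IUPAC ambiguity codes
    included) to N."""
    up = raw.upper()
    if set(up) <= _VALID:
        return up
    return "".join(c if c in _VALID else "N" for c in up)


@dataclass(frozen=True)
class GenomeSequence:
    chrom_name: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise FormatError(f"empty sequence for {self.chrom_name!r}")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read; lengths may differ between reads in one file."""

    read_id: str
    bases: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bases) < 1:
            raise FormatError(f"read {self.read_id!r} has empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise FormatError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class GeneModel:
    """One transcript of the UCSC refFlat dialect (0-based half-open)."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]

    @property
    def n_junctions(self) -> int:
        """Annotated internal (exon–exon) junctions: exon count − 1."""
        return len(self.exon_starts) - 1

    def junctions(self) -> list[tuple[int, int]]:
        """(intron start, intron end) pairs, i.e. (exon_ends[i], exon_starts[i+1])."""
        return [
            (self.exon_ends[i], self.exon_starts[i + 1])
            for i in range(len(self.exon_starts) - 1)
        ]

    def exonic_length(self) -> int:
        return sum(e - s for s, e in zip(self.exon_starts, self.exon_ends))


@dataclass(frozen=True)
class EstInterval:
    """EST alignment span, normalized to 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise FormatError(f"EST interval end {self.end} <= start {self.start}")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path) -> list[GenomeSequence]:
    """Parse a FASTA file into uppercase, N-normalized sequences.

    Duplicate headers and empty records are rejected.
    """
    out: list[GenomeSequence] = []
    seen: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:  # pragma: no cover - biopython message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    # detect junk before the first header, which SeqIO silently skips
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FormatError(f"{path}:{lineno}: expected FASTA header, got {line.strip()!r}")
            break
    for rec in records:
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        seen.add(rec.id)
        out.append(GenomeSequence(rec.id, _normalize_bases(str(rec.seq))))
    return out


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream 4-line FASTQ records in file order; variable lengths allowed."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if header == "":
                return
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise FormatError(f"{path}: expected '@' header, got {header!r}")
            bases = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            quals = fh.readline().rstrip("\n")
            read_id = header[1:].split()[0] if len(header) > 1 else ""
            if not plus.startswith("+"):
                raise FormatError(f"{path}: read {read_id!r}: missing '+' separator")
            if len(quals) != len(bases):
                raise FormatError(
                    f"{path}: read {read_id!r}: quality length {len(quals)} "
                    f"!= sequence length {len(bases)}"
                )
            yield ReadRecord(read_id, _normalize_bases(bases), quals)


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            q = r.qualities if r.qualities is not None else "I" * len(r.bases)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# refFlat


def read_refflat(path) -> list[GeneModel]:
    """Parse UCSC refFlat TSV (geneName, name, chrom, strand, txStart, txEnd,
    cdsStart, cdsEnd, exonCount, exonStarts, exonEnds).

    Coordinates are kept 0-based half-open, refFlat's native convention.
    """
    out: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise FormatError(f"{path}:{lineno}: expected 11 refFlat columns, got {len(fields)}")
            gene, name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            tx_start, tx_end = int(fields[4]), int(fields[5])
            exon_count = int(fields[8])
            starts = tuple(int(x) for x in fields[9].rstrip(",").split(",") if x)
            ends = tuple(int(x) for x in fields[10].rstrip(",").split(",") if x)
            if len(starts) != exon_count or len(ends) != exon_count:
                raise FormatError(
                    f"{path}:{lineno}: exonCount={exon_count} but {len(starts)} starts / "
                    f"{len(ends)} ends listed"
                )
            if any(s2 <= s1 for s1, s2 in zip(starts, starts[1:])):
                raise FormatError(f"{path}:{lineno}: exonStarts not strictly increasing")
            if any(e <= s for s, e in zip(starts, ends)):
                raise FormatError(f"{path}:{lineno}: empty or inverted exon")
            if any(starts[i + 1] < ends[i] for i in range(exon_count - 1)):
                raise FormatError(f"{path}:{lineno}: overlapping exons")
            if starts[0] < tx_start or ends[-1] > tx_end:
                raise FormatError(f"{path}:{lineno}: exons outside transcript span")
            out.append(GeneModel(gene, name, chrom, strand, tx_start, tx_end, starts, ends))
    return out


def write_refflat(models: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            starts = ",".join(str(s) for s in m.exon_starts) + ","
            ends = ",".join(str(e) for e in m.exon_ends) + ","
            fh.write(
                "\t".join(
                    [
                        m.gene_name,
                        m.transcript_id,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(m.tx_start),
                        str(m.tx_end),
                        str(len(m.exon_starts)),
                        starts,
                        ends,
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# EST intervals (GTF from the UCSC table browser, or BED)


def read_est_intervals(path, fmt: Optional[str] = None) -> list[EstInterval]:
    """Read EST alignment spans from GTF (1-based inclusive) or BED
    (0-based half-open), normalizing to internal 0-based half-open.

    ``fmt`` is 'gtf' or 'bed'; inferred from the file suffix when omitted.
    """
    if fmt is None:
        suffix = Path(path).suffix.lower()
        fmt = {"gtf": "gtf", "gff": "gtf", "bed": "bed"}.get(suffix.lstrip("."), None)
        if fmt is None:
            raise ValueError(f"cannot infer EST format from {path}; pass fmt='gtf'|'bed'")
    out: list[EstInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "gtf":
                    if len(fields) < 5:
                        raise FormatError(f"{path}:{lineno}: too few GTF columns")
                    chrom, start, end = fields[0], int(fields[3]) - 1, int(fields[4])
                elif fmt == "bed":
                    if len(fields) < 3:
                        raise FormatError(f"{path}:{lineno}: too few BED columns")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                else:
                    raise ValueError(f"unknown EST format {fmt!r}")
            except ValueError as exc:
                if isinstance(exc, FormatError):
                    raise
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            out.append(EstInterval(chrom, start, end))
    return out


def write_est_bed(ests: Iterable[EstInterval], path) -> None:
    with open(path, "w") as fh:
        for e in ests:
            fh.write(f"{e.chrom}\t{e.start}\t{e.end}\n")


# ---------------------------------------------------------------------------
# Junction outputs


def _chrom_sort_key(chrom: str):
    """Natural ordering so chr2 sorts before chr10."""
    core = chrom[3:] if chrom.startswith("chr") else chrom
    return (0, int(core)) if core.isdigit() else (1, core)


def write_junction_table(calls, path) -> None:
    """Write the tab-separated junction report.

    Boundaries are printed 1-based inclusive: for an internal junction with
    0-based half-open excision [left_end, right_start), the printed left
    boundary is ``left_end`` (last exonic base on the left, 1-based) and the
    printed right boundary is ``right_start + 1`` (first exonic base on the
    right, 1-based).
    """
    rows = sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.left_end, c.right_start))
    with open(path, "w") as fh:
        fh.write("\t".join(JUNCTION_TABLE_COLUMNS) + "\n")
        for c in rows:
            fh.write(
                "\t".join(
                    [
                        c.chrom,
                        str(c.left_end),
                        str(c.right_start + 1),
                        str(c.splice_length),
                        str(c.support),
                        c.novelty,
                        c.gene_name or ".",
                    ]
                )
                + "\n"
            )


def write_spliced_fasta(calls, genome: Iterable[GenomeSequence], path) -> None:
    """Export the excised (spliced-out) sequence of each call as FASTA.

    The record sequence is the genome slice [left_end, right_start); the
    header encodes chrom, 1-based boundaries and support so downstream
    search results can be traced back to the call.
    """
    by_name = {g.chrom_name: g for g in genome}
    records = []
    for c in sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.left_end, c.right_start)):
        if c.chrom not in by_name:
            raise ValueError(f"junction {c.chrom}:{c.left_end}-{c.right_start}: unknown chromosome")
        chrom = by_name[c.chrom]
        if c.right_start > len(chrom.bases) or c.left_end < 0:
            raise ValueError(
                f"junction {c.chrom}:{c.left_end}-{c.right_start} outside chromosome "
                f"(length {len(chrom.bases)})"
            )
        name = f"{c.chrom}|{c.left_end}|{c.right_start + 1}|support={c.support}"
        records.append((name, chrom.bases[c.left_end : c.right_start]))
    write_fasta(records, path)


def parse_spliced_fasta_id(name: str) -> tuple[str, int, int]:
    """Recover (chrom, left_end, right_start) in internal coordinates from a
    spliced-FASTA header written by :func:`write_spliced_fasta`."""
    chrom, left, right, _ = name.split("|")
    return chrom, int(left), int(right) - 1
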