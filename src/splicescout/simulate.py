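"""Deterministic synthetic test substrate: toy genomes, gene models,
planted junctions, junction-spanning reads, matched ESTs and query sets.

The generator emulates the situation the split-read caller is built for:
a strand-specific RNA-Seq library in which junction-spanning reads fail
contiguous alignment while exon-interior reads map directly.  Planted
junctions carry flanking sequence whose ``min_split``-length context is
unique in the genome (verified by exhaustive scanning, re-drawn on
collision), so every planted junction is recoverable by at least one
split position.  All randomness flows through one integer-only PCG64
stream per scenario seed, making outputs byte-identical across runs and
platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seqio import EstInterval, GeneModel, GenomeSequence, ReadRecord, revcomp
from .signatures import IntronRecord
from .splitting import select_min_split_size

__all__ = [
    "SimScenario",
    "TruthJunction",
    "SimData",
    "make_genome",
    "plant_junctions",
    "simulate_reads",
    "make_ests_and_queries",
    "simulate",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class SimScenario:
    """Study conditions for one synthetic dataset.

    Defaults describe a compact but non-trivial locus set: ten 3-exon
    genes (400 nt exons, 600 nt introns) on one chromosome, 50 nt
    error-free reads — the middle of the 34–101 nt range the caller
    supports — with 3 spanning reads per planted junction and 20 novel
    junctions excising 100–1000 nt.
    """

    seed: int = 0
    chrom_name: str = "chrSim"
    n_genes: int = 10
    exons_per_gene: int = 3
    exon_length: int = 400
    intron_length: int = 600
    intergenic: int = 400
    genome_length: Optional[int] = None  # computed from the layout when None
    read_length: int = 50
    n_contiguous_reads: int = 200
    spanning_support: int = 3
    n_novel: int = 20
    novel_distance: tuple[int, int] = (100, 1000)
    novel_distances: Optional[tuple[int, ...]] = None  # explicit per-junction splice lengths
    error_rate: float = 0.0
    reverse_fraction: float = 0.0  # strand-specific library by default
    min_split: Optional[int] = None  # None -> automatic read-length rule

    def resolved_min_split(self) -> int:
        return self.min_split if self.min_split is not None else select_min_split_size(self.read_length)

    def gene_span(self) -> int:
        return self.exons_per_gene * self.exon_length + (self.exons_per_gene - 1) * self.intron_length

    def required_length(self) -> int:
        return self.n_genes * (self.gene_span() + self.intergenic) + self.intergenic


@dataclass(frozen=True)
class TruthJunction:
    truth_id: str
    chrom: str
    left_end: int
    right_start: int
    support: int
    klass: str  # 'annotated' | 'novel'
    spliced_sequence: str

    @property
    def splice_length(self) -> int:
        return self.right_start - self.left_end


@dataclass
class SimData:
    scenario: SimScenario
    genome: list[GenomeSequence]
    genes: list[GeneModel]
    truths: list[TruthJunction]
    reads: list[ReadRecord]
    truth_of_read: dict[str, str]  # spanning read id -> truth id
    ests: list[EstInterval] = field(default_factory=list)
    introns: list[IntronRecord] = field(default_factory=list)
    mirnas: list[tuple[str, str]] = field(default_factory=list)


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _occurrences(genome: str, pattern: str) -> int:
    """Occurrences of pattern on both strands of the genome."""
    count = 0
    for hay in (genome, revcomp(genome)):
        pos = hay.find(pattern)
        while pos != -1:
            count += 1
            pos = hay.find(pattern, pos + 1)
    return count


def make_genome(scenario: SimScenario) -> tuple[list[GenomeSequence], list[GeneModel]]:
    """Uniform-random genome with non-overlapping genes of the stated exon
    structure; gene strands alternate +/-.  Errors if the requested genome
    length cannot fit the genes."""
    required = scenario.required_length()
    length = scenario.genome_length if scenario.genome_length is not None else required
    if length < required:
        raise ValueError(
            f"genome_length {length} too small for {scenario.n_genes} genes (need {required})"
        )
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.Generator(np.random.PCG64(scenario.seed))
    bases = _random_bases(rng, length)
    genome = [GenomeSequence(scenario.chrom_name, bases)]
    genes: list[GeneModel] = []
    pos = scenario.intergenic
    for gi in range(scenario.n_genes):
        starts, ends = [], []
        cursor = pos
        for _ in range(scenario.exons_per_gene):
            starts.append(cursor)
            cursor += scenario.exon_length
            ends.append(cursor)
            cursor += scenario.intron_length
        tx_end = ends[-1]
        strand = "+" if gi % 2 == 0 else "-"
        genes.append(
            GeneModel(
                gene_name=f"GENE{gi:03d}",
                transcript_id=f"TX{gi:03d}",
                chrom=scenario.chrom_name,
                strand=strand,
                tx_start=pos,
                tx_end=tx_end,
                exon_starts=tuple(starts),
                exon_ends=tuple(ends),
            )
        )
        pos = tx_end + scenario.intergenic
    return genome, genes


def plant_junctions(
    scenario: SimScenario,
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    max_retries: int = 200,
) -> list[TruthJunction]:
    """Annotated truths (every exon-exon junction) plus ``n_novel`` novel
    junctions placed inside gene spans at distances drawn from the
    scenario, with both min_split-length flanks unique genome-wide
    (re-drawn on collision, bounded retries)."""
    rng = np.random.Generator(np.random.PCG64(scenario.seed + 1))
    bases = genome[0].bases
    ms = scenario.resolved_min_split()
    margin = scenario.read_length
    truths: list[TruthJunction] = []

    def flanks_unique(left_end: int, right_start: int) -> bool:
        left_flank = bases[left_end - ms : left_end]
        right_flank = bases[right_start : right_start + ms]
        return _occurrences(bases, left_flank) == 1 and _occurrences(bases, right_flank) == 1

    for g in genes:
        for ji, (le, rs) in enumerate(g.junctions()):
            if not flanks_unique(le, rs):
                raise ValueError(
                    "annotated junction flank not unique; use a longer genome or another seed"
                )
            truths.append(
                TruthJunction(
                    f"ann|{g.gene_name}|{ji}",
                    g.chrom,
                    le,
                    rs,
                    scenario.spanning_support,
                    "annotated",
                    bases[le:rs],
                )
            )

    lo_d, hi_d = scenario.novel_distance
    explicit = scenario.novel_distances
    if explicit is not None and len(explicit) != scenario.n_novel:
        raise ValueError("novel_distances must list one splice length per novel junction")
    for ni in range(scenario.n_novel):
        g = genes[ni % len(genes)]
        span = g.tx_end - g.tx_start
        # feasible distance range inside this gene span with read-length margins
        feasible_hi = span - 2 * margin
        if explicit is not None:
            if explicit[ni] > feasible_hi or explicit[ni] < 1:
                raise ValueError(
                    f"requested splice length {explicit[ni]} does not fit in gene span {span}"
                )
            lo = hi = explicit[ni]
        else:
            hi = min(hi_d, feasible_hi)
            lo = max(min(lo_d, hi), 2)
        placed = False
        for _ in range(max_retries):
            d = int(rng.integers(lo, hi + 1))
            left_end = int(rng.integers(g.tx_start + margin, g.tx_end - margin - d + 1))
            right_start = left_end + d
            if flanks_unique(left_end, right_start):
                truths.append(
                    TruthJunction(
                        f"nov|{g.gene_name}|{ni}",
                        g.chrom,
                        left_end,
                        right_start,
                        scenario.spanning_support,
                        "novel",
                        bases[left_end:right_start],
                    )
                )
                placed = True
                break
        if not placed:
            raise ValueError("could not place a novel junction with unique flanks; use a longer genome")
    return truths


def simulate_reads(
    scenario: SimScenario,
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    truths: Sequence[TruthJunction],
) -> tuple[list[ReadRecord], dict[str, str]]:
    """Spanning reads (``support`` per truth, flank offsets uniform among
    those leaving >= min_split on both sides) plus contiguous exon-interior
    reads; returns the reads and the spanning-read -> truth map."""
    rng = np.random.Generator(np.random.PCG64(scenario.seed + 2))
    bases = genome[0].bases
    L = scenario.read_length
    ms = scenario.resolved_min_split()
    err_ppm = int(round(scenario.error_rate * 1_000_000))
    rev_ppm = int(round(scenario.reverse_fraction * 1_000_000))
    reads: list[ReadRecord] = []
    truth_of_read: dict[str, str] = {}

    def mutate(seq: str) -> str:
        if err_ppm == 0:
            return seq
        chars = list(seq)
        for i in range(len(chars)):
            if rng.integers(0, 1_000_000) < err_ppm:
                chars[i] = _BASES[(_BASES.index(chars[i]) + 1 + int(rng.integers(0, 3))) % 4]
        return "".join(chars)

    for t in truths:
        for ri in range(t.support):
            offset = int(rng.integers(ms, L - ms + 1))  # left-flank length
            seq = bases[t.left_end - offset : t.left_end] + bases[t.right_start : t.right_start + L - offset]
            seq = mutate(seq)
            if rev_ppm and rng.integers(0, 1_000_000) < rev_ppm:
                seq = revcomp(seq)
            rid = f"span|{t.truth_id}|{ri}"
            reads.append(ReadRecord(rid, seq))
            truth_of_read[rid] = t.truth_id

    # contiguous exon-interior reads (map in the initial phase; RPKM substrate)
    exons = [
        (g.chrom, s, e)
        for g in genes
        for s, e in zip(g.exon_starts, g.exon_ends)
        if e - s >= L
    ]
    for ci in range(scenario.n_contiguous_reads):
        chrom, s, e = exons[int(rng.integers(0, len(exons)))]
        start = int(rng.integers(s, e - L + 1))
        seq = mutate(bases[start : start + L])
        if rev_ppm and rng.integers(0, 1_000_000) < rev_ppm:
            seq = revcomp(seq)
        reads.append(ReadRecord(f"cont|{ci}", seq))
    return reads, truth_of_read


def make_ests_and_queries(
    scenario: SimScenario,
    genome: Sequence[GenomeSequence],
    genes: Sequence[GeneModel],
    truths: Sequence[TruthJunction],
    est_length: int = 120,
    n_decoy_mirnas: int = 10,
    mirna_length: int = 22,
    branch_offset: int = 30,
) -> tuple[list[EstInterval], list[IntronRecord], list[tuple[str, str]]]:
    """Fixtures for the validation and signature machinery.

    For every truth one EST ends exactly at its left boundary and one
    starts exactly at its right boundary (so any buffer >= 0 validates).
    Intron records mirror the annotated introns with alternating U12/U2
    type (branch point ``branch_offset`` nt from the 3' end, transcript
    orientation, for U12).  miRNA queries are random decoy k-mers plus
    positive controls copied from excised truth sequences.
    """
    rng = np.random.Generator(np.random.PCG64(scenario.seed + 3))
    chrom = genome[0].chrom_name
    chrom_len = len(genome[0].bases)
    ests: list[EstInterval] = []
    for t in truths:
        ests.append(EstInterval(chrom, max(0, t.left_end - est_length), t.left_end))
        ests.append(EstInterval(chrom, t.right_start, min(chrom_len, t.right_start + est_length)))

    introns: list[IntronRecord] = []
    idx = 0
    for g in genes:
        for le, rs in g.junctions():
            stype = "U12" if idx % 2 == 0 else "U2"
            bp = None
            if stype == "U12":
                bp = rs - 1 - (branch_offset - 1) if g.strand == "+" else le + branch_offset - 1
            introns.append(IntronRecord(f"intron{idx:03d}", g.chrom, g.strand, le, rs, stype, bp))
            idx += 1

    mirnas: list[tuple[str, str]] = []
    controls = [t for t in truths if t.splice_length >= mirna_length]
    for i, t in enumerate(controls[:2]):
        start = (t.splice_length - mirna_length) // 2
        mirnas.append((f"mir-control-{i}", t.spliced_sequence[start : start + mirna_length]))
    for i in range(n_decoy_mirnas):
        mirnas.append((f"mir-decoy-{i}", _random_bases(rng, mirna_length)))
    return ests, introns, mirnas


def simulate(scenario: SimScenario) -> SimData:
    """Run the full generator: genome, genes, truths, reads, ESTs, introns
    and miRNA queries, all derived deterministically from the seed."""
    genome, genes = make_genome(scenario)
    truths = plant_junctions(scenario, genome, genes)
    reads, truth_of_read = simulate_reads(scenario, genome, genes, truths)
    ests, introns, mirnas = make_ests_and_queries(scenario, genome, genes, truths)
    return SimData(scenario, genome, genes, truths, reads, truth_of_read, ests, introns, mirnas)


def write_sim_files(data: SimData, outdir) -> dict[str, str]:
    """Emit FASTA/FASTQ/refFlat/BED/truth-TSV files consumable by the
    pipeline unmodified; returns {kind: path}."""
    from pathlib import Path

    from .seqio import write_est_bed, write_fasta, write_fastq, write_refflat

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fasta",
        "reads": outdir / "reads.fastq",
        "refflat": outdir / "annotation.refflat",
        "ests": outdir / "ests.bed",
        "truth": outdir / "truth.tsv",
        "mirnas": outdir / "mirnas.fasta",
    }
    write_fasta([(g.chrom_name, g.bases) for g in data.genome], paths["genome"])
    write_fastq(data.reads, paths["reads"])
    write_refflat(data.genes, paths["refflat"])
    write_est_bed(data.ests, paths["ests"])
    write_fasta(data.mirnas, paths["mirnas"])
    with open(paths["truth"], "w") as fh:
        fh.write("truth_id\tchrom\tleft_end\tright_start\tsplice_length\tsupport\tclass\n")
        for t in data.truths:
            fh.write(
                f"{t.truth_id}\t{t.chrom}\t{t.left_end}\t{t.right_start}\t"
                f"{t.splice_length}\t{t.support}\t{t.klass}\n"
            )
    return {k: str(v) for k, v in paths.items()}
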