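"""Pipeline orchestration: configuration, the analytic and comparison
modes, stage accounting and intermediate-file hygiene.

The analytic mode runs the full chain — initial contiguous alignment,
splitting of unmapped reads, exact part alignment, matched-pair
formation, buffered support clustering, long-side rescue, junction
calling — and writes the junction table, the excised-sequence FASTA, a
resolved-config echo and a stage log.  Comparison mode runs two analytic
passes and reports common/unique junctions.
"""

from __future__ import annotations

import json
import logging
import time
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

from . import align as al
from . import junctions as jc
from .seqio import (
    GeneModel,
    GenomeSequence,
    ReadRecord,
    read_fasta,
    read_fastq,
    read_refflat,
    write_junction_table,
    write_spliced_fasta,
)
from .splitting import SplitConfig, enumerate_splits

__all__ = ["PipelineConfig", "AnalyticResult", "run_analytic", "run_analytic_data", "run_comparison"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    mode: str = "analytic"  # 'analytic' | 'comparison'
    supp: int = jc.DEFAULT_SUPP
    min_d: int = jc.DEFAULT_MIN_D
    max_d: int = jc.DEFAULT_MAX_D
    max_alignments: int = 2
    min_split_size: Optional[int] = None  # None -> automatic read-length rule
    buffer: int = jc.DEFAULT_BUFFER
    engine: str = "internal"  # initial-phase engine: 'internal' | 'external'
    external_command: Optional[str] = None
    known_tolerance: int = 0
    genome: Optional[str] = None
    reads: Optional[str] = None
    reads_b: Optional[str] = None  # second dataset, comparison mode
    refflat: Optional[str] = None
    est: Optional[str] = None
    outdir: Optional[str] = None
    keep_intermediates: bool = False
    seed: int = 0  # reserved for randomized tie-breaking; none by default

    def validate(self) -> None:
        if self.mode not in ("analytic", "comparison"):
            raise ValueError("mode must be 'analytic' or 'comparison'")
        if self.min_d > self.max_d:
            raise ValueError("min_d must be <= max_d")
        if self.supp < 1:
            raise ValueError("supp must be >= 1")
        if self.min_split_size is not None and self.min_split_size < 1:
            raise ValueError("min_split_size must be >= 1 (or None for the automatic rule)")
        if self.max_alignments < 1:
            raise ValueError("max_alignments must be >= 1")
        if self.buffer < 0:
            raise ValueError("buffer must be >= 0")


@dataclass
class AnalyticResult:
    calls: list
    candidates: list
    pairs: list
    stage_counts: dict
    mapped_hits: dict  # read_id -> representative initial-phase hit


def run_analytic_data(
    genome: Sequence[GenomeSequence],
    reads: Sequence[ReadRecord],
    genes: Sequence[GeneModel],
    config: Optional[PipelineConfig] = None,
) -> AnalyticResult:
    """Run the analytic pipeline on in-memory inputs.

    This is the library entry point; :func:`run_analytic` wraps it with
    file I/O.  Stage accounting is asserted: reads_in = mapped + unmapped
    and unmapped = split-eligible + too-short.
    """
    config = config or PipelineConfig()
    config.validate()
    reads = list(reads)
    split_cfg = SplitConfig(config.min_split_size)
    if reads:
        k = min(split_cfg.resolve(len(r)) for r in reads)
    else:
        k = config.min_split_size or 15
    t0 = time.time()
    index = al.build_index(genome, k)
    logger.info("stage=index k=%d seconds=%.2f", k, time.time() - t0)

    t0 = time.time()
    mapped_hits, unmapped = al.initial_align_hits(reads, index)
    counts = {"reads_in": len(reads), "mapped": len(mapped_hits), "unmapped": len(unmapped)}
    assert counts["reads_in"] == counts["mapped"] + counts["unmapped"]
    logger.info(
        "stage=initial_align reads_in=%d mapped=%d unmapped=%d seconds=%.2f",
        counts["reads_in"], counts["mapped"], counts["unmapped"], time.time() - t0,
    )

    # split and align parts of unmapped reads
    t0 = time.time()
    part_results: dict[tuple[str, int], dict[str, al.AlignResult]] = defaultdict(dict)
    part_lengths: dict[str, dict[tuple[int, str], int]] = defaultdict(dict)
    too_short = 0
    n_parts = 0
    for read in unmapped:
        ms = split_cfg.resolve(len(read))
        if len(read) < 2 * ms:
            too_short += 1
            continue
        for part in enumerate_splits(read, ms):
            res = al.align_exact(part, index, config.max_alignments)
            part_results[(read.read_id, part.split_position)][part.side] = res
            part_lengths[read.read_id][(part.split_position, part.side)] = len(part)
            n_parts += 1
    counts["too_short"] = too_short
    counts["split_eligible"] = len(unmapped) - too_short
    counts["parts_aligned"] = n_parts
    assert counts["unmapped"] == counts["split_eligible"] + counts["too_short"]
    logger.info(
        "stage=split_align split_eligible=%d too_short=%d parts=%d seconds=%.2f",
        counts["split_eligible"], too_short, n_parts, time.time() - t0,
    )

    t0 = time.time()
    gene_index = jc.GeneIndex(genes)
    pairs = jc.form_matched_pairs(part_results, gene_index, config.min_d, config.max_d)
    counts["matched_pairs"] = len(pairs)
    candidates = jc.cluster_support(pairs, config.buffer)
    counts["candidates"] = len(candidates)

    # long-side rescue: reads with zero matched pairs whose one side was
    # suppressed for multi-mapping but whose longer side mapped
    paired_reads = {p.read_id for p in pairs}
    rescue_hits: list[jc.RescueHit] = []
    for (read_id, p), sides in part_results.items():
        if read_id in paired_reads:
            continue
        for side, other in (("L", "R"), ("R", "L")):
            res, other_res = sides.get(side), sides.get(other)
            if res is None or other_res is None:
                continue
            if res.status != al.UNIQUE_HITS or other_res.status != al.SUPPRESSED_MULTI:
                continue
            lengths = part_lengths[read_id]
            if lengths[(p, side)] < lengths[(p, other)]:
                continue  # only the longer side rescues
            rescue_hits.extend(jc.RescueHit(read_id, side, h) for h in res.hits)
    candidates = jc.rescue_long_sides(rescue_hits, candidates, config.buffer)
    counts["rescued_reads"] = sum(c.rescue_support for c in candidates)

    calls = jc.call_junctions(
        candidates, genome, config.supp, annotation=genes, known_tolerance=config.known_tolerance
    )
    counts["calls"] = len(calls)
    for c in calls:
        assert c.support >= config.supp
        assert config.min_d <= c.splice_length <= config.max_d
    logger.info(
        "stage=call pairs=%d candidates=%d rescued=%d calls=%d seconds=%.2f",
        len(pairs), len(candidates), counts["rescued_reads"], len(calls), time.time() - t0,
    )
    return AnalyticResult(calls, candidates, pairs, counts, mapped_hits)


def _load_inputs(config: PipelineConfig):
    for name in ("genome", "reads", "refflat"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    genome = read_fasta(config.genome)
    reads = list(read_fastq(config.reads))
    genes = read_refflat(config.refflat)
    return genome, reads, genes


def run_analytic(config: PipelineConfig) -> AnalyticResult:
    """File-based analytic run: reads inputs, executes the pipeline, writes
    junctions.tsv, spliced.fasta, config.json and stages.json to outdir.

    Intermediate alignment artifacts (external-engine part files) are
    deleted on success unless ``keep_intermediates`` is set; on failure
    they are retained for debugging.
    """
    config.validate()
    if config.outdir is None:
        raise ValueError("outdir is required for file-based runs")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, reads, genes = _load_inputs(config)
    if config.engine == "external":
        # mismatch-tolerant initial phase via the external adapter; only its
        # unmapped partition proceeds (the split phase is always internal)
        ext = al.ExternalAligner(config.external_command or "", workdir=None if config.keep_intermediates else None)
        _, reads = ext.partition(reads)
    result = run_analytic_data(genome, reads, genes, config)

    write_junction_table(result.calls, outdir / "junctions.tsv")
    write_spliced_fasta(result.calls, genome, outdir / "spliced.fasta")
    with open(outdir / "config.json", "w") as fh:
        json.dump(asdict(config), fh, indent=2, sort_keys=True)
    with open(outdir / "stages.json", "w") as fh:
        json.dump(result.stage_counts, fh, indent=2, sort_keys=True)
    return result


def run_comparison(config: PipelineConfig) -> dict:
    """Two analytic runs plus a common/unique junction report.

    ``reads`` and ``reads_b`` name the two datasets; per-dataset outputs
    land in outdir/a and outdir/b, the comparison in comparison.tsv.
    """
    config.validate()
    if config.reads_b is None:
        raise ValueError("comparison mode requires reads_b")
    outdir = Path(config.outdir or ".")
    from dataclasses import replace

    cfg_a = replace(config, mode="analytic", outdir=str(outdir / "a"))
    cfg_b = replace(config, mode="analytic", outdir=str(outdir / "b"), reads=config.reads_b)
    res_a = run_analytic(cfg_a)
    res_b = run_analytic(cfg_b)
    comparison = jc.compare_runs(res_a.calls, res_b.calls, config.buffer)
    with open(outdir / "comparison.tsv", "w") as fh:
        fh.write("status\tchrom\tleft_a\tright_a\tleft_b\tright_b\n")
        for a, b in comparison["common"]:
            fh.write(
                f"common\t{a.chrom}\t{a.left_end}\t{a.right_start + 1}\t{b.left_end}\t{b.right_start + 1}\n"
            )
        for c in comparison["unique_a"]:
            fh.write(f"unique_a\t{c.chrom}\t{c.left_end}\t{c.right_start + 1}\t.\t.\n")
        for c in comparison["unique_b"]:
            fh.write(f"unique_b\t{c.chrom}\t.\t.\t{c.left_end}\t{c.right_start + 1}\n")
    return {"a": res_a, "b": res_b, "comparison": comparison}
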