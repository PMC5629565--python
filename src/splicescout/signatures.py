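"""Splice-signature and miRNA search against excised junction sequences.

Query construction follows the five signature categories used for
minor/major spliceosome introns: the 3' acceptor context (last 40
intronic nt + first 6 nt of the downstream exon, 46 nt), the 5' donor
context (last 10 nt of the upstream exon + first 15 intronic nt, 25 nt),
and — for U12-type introns only — the branch-site context (from 10 nt
upstream of the branch point through the intron's 3'-terminal base).
Minus-strand introns are reverse-complemented so queries read 5'->3' of
the transcript.

The search engine is a seeded local aligner scored like the nucleotide
BLAST run it emulates (match +1, mismatch -1, gap of length g costs
2 + 2g); e-values come from the Karlin-Altschul formula E = K*m*n*
exp(-lambda*S) with lambda and K computed for the +-1 two-valued score
under the subject base composition.  Agreement with NCBI BLAST e-values
is not promised; scores are exact local-alignment optima.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from Bio import Align

from .seqio import GenomeSequence, revcomp

__all__ = [
    "IntronRecord",
    "SpliceQuery",
    "SearchHit",
    "Scoring",
    "CATEGORIES",
    "build_queries",
    "search",
    "karlin_altschul_params",
    "local_align_score",
    "tabulate_by_category",
    "tabulate_mirna",
    "DEFAULT_E_THRESHOLD",
]

logger = logging.getLogger(__name__)

CATEGORIES = ("3pFull_u12", "3pFull_u2", "5pFull_u12", "5pFull_u2", "branch_u12")
DEFAULT_E_THRESHOLD = 0.001

# context extents (nt)
ACCEPTOR_INTRONIC = 40
ACCEPTOR_EXONIC = 6
DONOR_INTRONIC = 15
DONOR_EXONIC = 10
BRANCH_UPSTREAM = 10


@dataclass(frozen=True)
class IntronRecord:
    """One database intron; interval is 0-based half-open genomic."""

    intron_id: str
    chrom: str
    strand: str
    start: int
    end: int
    spliceosome_type: str  # 'U12' | 'U2'
    branch_point: Optional[int] = None  # genomic coordinate of the branch base

    def __post_init__(self) -> None:
        if self.branch_point is not None and not (self.start <= self.branch_point < self.end):
            raise ValueError(f"intron {self.intron_id}: branch point outside intron")


@dataclass(frozen=True)
class SpliceQuery:
    query_id: str
    category: str
    bases: str


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    subject_id: str
    score: int
    e_value: float
    subject_start: int
    subject_end: int


@dataclass(frozen=True)
class Scoring:
    """Gap of length g costs gap_open + g * gap_extend (subtracted)."""

    match: int = 1
    mismatch: int = -1
    gap_open: int = 2
    gap_extend: int = 2


def _category_for(intron: IntronRecord, kind: str) -> str:
    return f"{kind}_{intron.spliceosome_type.lower()}"


def build_queries(
    introns: Sequence[IntronRecord],
    genome: Sequence[GenomeSequence],
    categories: Iterable[str] = CATEGORIES,
) -> list[SpliceQuery]:
    """Build signature queries for each intron and requested category.

    Records whose context overruns the chromosome are skipped with a
    logged warning.  A branch category is only defined for U12-type
    introns; requesting 'branch_u2' raises.
    """
    categories = set(categories)
    if "branch_u2" in categories:
        raise ValueError("branch queries are defined for U12-type introns only")
    unknown = categories - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    chroms = {g.chrom_name: g.bases for g in genome}
    out: list[SpliceQuery] = []
    for intron in introns:
        bases = chroms.get(intron.chrom)
        if bases is None:
            logger.warning("intron %s: unknown chromosome %s; skipped", intron.intron_id, intron.chrom)
            continue
        for kind in ("5pFull", "3pFull", "branch"):
            cat = _category_for(intron, kind)
            if cat not in categories:
                continue
            seq = _extract_context(intron, bases, kind)
            if seq is None:
                logger.warning(
                    "intron %s: %s context overruns chromosome; skipped", intron.intron_id, kind
                )
                continue
            out.append(SpliceQuery(f"{intron.intron_id}|{cat}", cat, seq))
    return out


def _extract_context(intron: IntronRecord, bases: str, kind: str) -> Optional[str]:
    s, e, L = intron.start, intron.end, len(bases)
    if intron.strand == "+":
        if kind == "5pFull":
            lo, hi = s - DONOR_EXONIC, s + DONOR_INTRONIC
        elif kind == "3pFull":
            lo, hi = e - ACCEPTOR_INTRONIC, e + ACCEPTOR_EXONIC
        else:  # branch
            if intron.branch_point is None:
                return None
            lo, hi = intron.branch_point - BRANCH_UPSTREAM, e
        if lo < 0 or hi > L or hi <= lo:
            return None
        return bases[lo:hi]
    # minus strand: transcript 5' donor is at the genomic end of the interval
    if kind == "5pFull":
        lo, hi = e - DONOR_INTRONIC, e + DONOR_EXONIC
    elif kind == "3pFull":
        lo, hi = s - ACCEPTOR_EXONIC, s + ACCEPTOR_INTRONIC
    else:
        if intron.branch_point is None:
            return None
        lo, hi = s, intron.branch_point + BRANCH_UPSTREAM + 1
    if lo < 0 or hi > L or hi <= lo:
        return None
    return revcomp(bases[lo:hi])


# ---------------------------------------------------------------------------
# Search engine


def karlin_altschul_params(subject_bases: Iterable[str]) -> tuple[float, float]:
    """(lambda, K) for the two-valued +1/-1 score under the subject base
    composition.

    With match probability p = sum_i f_i^2 and q = 1 - p, lambda is the
    positive root of p*e^l + q*e^-l = 1 (closed form ln of the larger root
    of p*x^2 - x + q = 0) and K uses the lattice closed form (q - p)^2 / q.
    For uniform composition: lambda = ln 3, K = 1/3.
    """
    counts = defaultdict(int)
    total = 0
    for seq in subject_bases:
        for c in seq:
            if c in "ACGT":
                counts[c] += 1
                total += 1
    if total == 0:
        return math.log(3.0), 1.0 / 3.0
    p = sum((n / total) ** 2 for n in counts.values())
    if p >= 0.5:
        # expected score non-negative: no finite lambda for this composition;
        # fall back to the uniform-composition parameters
        return math.log(3.0), 1.0 / 3.0
    q = 1.0 - p
    x = (1.0 + math.sqrt(1.0 - 4.0 * p * q)) / (2.0 * p)
    return math.log(x), (q - p) ** 2 / q


def _make_aligner(scoring: Scoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # first gapped position pays open + extend under the cost(g) = open + g*extend rule
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def local_align_score(query: str, subject: str, scoring: Scoring = Scoring()) -> int:
    """Optimal local alignment score of query vs one subject orientation."""
    if not query or not subject:
        return 0
    return int(_make_aligner(scoring).score(subject, query))


def _seed_match(query: str, subject: str, k: int) -> bool:
    if len(query) < k or len(subject) < k:
        return False
    seeds = {query[i : i + k] for i in range(len(query) - k + 1)}
    return any(subject[i : i + k] in seeds for i in range(len(subject) - k + 1))


def search(
    queries: Sequence[SpliceQuery],
    subjects: Sequence[tuple[str, str]],
    scoring: Scoring = Scoring(),
    e_threshold: float = DEFAULT_E_THRESHOLD,
    seed_length: int = 7,
) -> list[SearchHit]:
    """Search every query against every subject (both strands), keeping the
    best-scoring local alignment per (query, subject) with e-value at or
    below ``e_threshold``.

    Subjects are (id, sequence) pairs — typically the excised-sequence
    FASTA records exported by the junction caller.  A pair is only aligned
    when query and subject share an exact ``seed_length``-mer on at least
    one strand; an empty subject database yields an empty result.
    """
    if not subjects:
        return []
    lam, K = karlin_altschul_params(seq for _, seq in subjects)
    n_db = sum(len(seq) for _, seq in subjects)
    aligner = _make_aligner(scoring)
    hits: list[SearchHit] = []
    for q in queries:
        if not q.bases:
            continue
        for sid, sseq in subjects:
            best: Optional[tuple[int, int, int]] = None  # score, sstart, send
            for oriented, forward in ((sseq, True), (revcomp(sseq), False)):
                if not _seed_match(q.bases, oriented, seed_length):
                    continue
                alns = aligner.align(oriented, q.bases)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                score = int(aln.score)
                blocks = aln.aligned[0]
                if len(blocks) == 0:
                    continue
                s0, s1 = int(blocks[0][0]), int(blocks[-1][1])
                if not forward:
                    s0, s1 = len(sseq) - s1, len(sseq) - s0
                if best is None or score > best[0]:
                    best = (score, s0, s1)
            if best is None:
                continue
            score, s0, s1 = best
            e_value = K * len(q.bases) * n_db * math.exp(-lam * score)
            if e_value <= e_threshold:
                hits.append(SearchHit(q.query_id, sid, score, e_value, s0, s1))
    hits.sort(key=lambda h: (h.query_id, h.subject_id))
    return hits


# ---------------------------------------------------------------------------
# Tabulation


def tabulate_by_category(
    hits: Sequence[SearchHit],
    queries: Sequence[SpliceQuery],
    subject_novelty: Mapping[str, str],
) -> "pandas.DataFrame":
    """Contingency table of distinct junctions hit, category x novelty.

    ``subject_novelty`` maps each subject (junction) id to 'known' or
    'novel'; a junction hit by several queries of one category counts once
    in that cell.  Row and column totals are appended.
    """
    import pandas as pd

    cat_of = {q.query_id: q.category for q in queries}
    cells: dict[tuple[str, str], set[str]] = defaultdict(set)
    for h in hits:
        if h.subject_id not in subject_novelty:
            raise KeyError(f"subject id {h.subject_id!r} has no junction-call mapping")
        cat = cat_of.get(h.query_id)
        if cat is None:
            raise KeyError(f"query id {h.query_id!r} not in query set")
        cells[(cat, subject_novelty[h.subject_id])].add(h.subject_id)
    table = pd.DataFrame(
        0, index=list(CATEGORIES), columns=["known", "novel"], dtype=int
    )
    for (cat, nov), subjects in cells.items():
        table.loc[cat, nov] = len(subjects)
    table["total"] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


def tabulate_mirna(per_sample_hits: Mapping[str, Sequence[SearchHit]]) -> "pandas.DataFrame":
    """Per-miRNA hit summary across samples.

    Returns a DataFrame indexed by miRNA (query) id with columns
    ``total_hits`` (hit count summed over samples) and
    ``samples_with_hit``, sorted descending by samples_with_hit then by
    id.  miRNAs with no hits anywhere are omitted; samples with zero hits
    contribute nothing.
    """
    import pandas as pd

    totals: dict[str, int] = defaultdict(int)
    samples: dict[str, set[str]] = defaultdict(set)
    for sample, hits in per_sample_hits.items():
        for h in hits:
            totals[h.query_id] += 1
            samples[h.query_id].add(sample)
    rows = [
        {"mirna": qid, "total_hits": totals[qid], "samples_with_hit": len(samples[qid])}
        for qid in totals
    ]
    df = pd.DataFrame(rows, columns=["mirna", "total_hits", "samples_with_hit"])
    if not df.empty:
        df = df.sort_values(
            ["samples_with_hit", "mirna"], ascending=[False, True], ignore_index=True
        )
    return df.set_index("mirna")
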