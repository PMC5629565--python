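"""Matched pairs, buffered clustering, rescue, calling, run comparison."""

import numpy as np
import pytest

from splicescout.align import AlignmentHit, AlignResult, SUPPRESSED_MULTI, UNIQUE_HITS
from splicescout.junctions import (
    GeneIndex,
    JunctionCandidate,
    MatchedPair,
    RescueHit,
    call_junctions,
    cluster_support,
    cluster_support_bruteforce,
    compare_runs,
    form_matched_pairs,
    rescue_long_sides,
)
from splicescout.seqio import GeneModel, GenomeSequence


def _gene(name="G1", chrom="chr1", start=0, end=10_000, strand="+"):
    return GeneModel(name, name + "t", chrom, strand, start, end, (start,), (end,))


def _results(read_id, p, left_hits, right_hits, left_status=UNIQUE_HITS, right_status=UNIQUE_HITS):
    lid, rid = f"{read_id}|p={p}|L", f"{read_id}|p={p}|R"
    return {
        (read_id, p): {
            "L": AlignResult(lid, left_status, tuple(AlignmentHit(lid, *h) for h in left_hits)),
            "R": AlignResult(rid, right_status, tuple(AlignmentHit(rid, *h) for h in right_hits)),
        }
    }


def _pair(read_id="r", p=20, chrom="chr1", strand="+", left=(100, 125), right=(225, 250), gene="G1"):
    return MatchedPair(read_id, p, chrom, strand, left, right, gene)


class TestFormMatchedPairs:
    GENES = [_gene()]

    def test_in_gene_in_window(self):
        res = _results("r1", 25, [("chr1", "+", 100, 125)], [("chr1", "+", 225, 250)])
        (pair,) = form_matched_pairs(res, self.GENES)
        assert pair.gap == 100
        assert (pair.left_end, pair.right_start) == (125, 225)

    def test_gap_below_min_d_rejected(self):
        res = _results("r1", 25, [("chr1", "+", 100, 125)], [("chr1", "+", 126, 151)])
        assert form_matched_pairs(res, self.GENES, min_d=2) == []

    def test_different_chromosomes_rejected(self):
        genes = [_gene(), _gene("G2", chrom="chr2")]
        res = _results("r1", 25, [("chr1", "+", 100, 125)], [("chr2", "+", 225, 250)])
        assert form_matched_pairs(res, genes) == []

    def test_no_common_gene_rejected(self):
        genes = [_gene("A", start=0, end=200), _gene("B", start=300, end=600)]
        res = _results("r1", 25, [("chr1", "+", 100, 125)], [("chr1", "+", 400, 425)])
        assert form_matched_pairs(res, genes) == []

    def test_minus_strand_roles_flip(self):
        # on '-', the read's left part sits genomically right of its right part
        res = _results("r1", 25, [("chr1", "-", 500, 525)], [("chr1", "-", 100, 125)])
        (pair,) = form_matched_pairs(res, self.GENES)
        assert (pair.left_end, pair.right_start) == (125, 500)
        assert pair.strand == "-"

    def test_suppressed_side_yields_no_pair(self):
        res = _results(
            "r1", 25, [("chr1", "+", 100, 125)], [], right_status=SUPPRESSED_MULTI
        )
        assert form_matched_pairs(res, self.GENES) == []

    def test_smallest_containing_gene_wins(self):
        genes = [_gene("BIG", start=0, end=10_000), _gene("SMALL", start=50, end=400)]
        res = _results("r1", 25, [("chr1", "+", 100, 125)], [("chr1", "+", 225, 250)])
        (pair,) = form_matched_pairs(res, genes)
        assert pair.gene_name == "SMALL"


class TestClusterSupport:
    def test_wobble_absorbed_into_most_frequent_anchor(self):
        pairs = [_pair(f"r{i}", left=(80, 100), right=(200, 220)) for i in range(3)]
        pairs.append(_pair("r3", left=(83, 103), right=(203, 223)))
        (cand,) = cluster_support(pairs, buffer=5)
        assert (cand.left_end, cand.right_start) == (100, 200)
        assert len(cand.members) == 4

    def test_right_offset_six_splits(self):
        pairs = [_pair("a", right=(206, 230)), _pair("b", right=(200, 224))]
        cands = cluster_support(pairs, buffer=5)
        assert len(cands) == 2

    def test_buffer_boundary_inclusive(self):
        pairs = [_pair("a", left=(80, 100), right=(200, 220)), _pair("b", left=(85, 105), right=(200, 220))]
        assert len(cluster_support(pairs, buffer=5)) == 1

    def test_strands_never_mix(self):
        pairs = [_pair("a"), _pair("b", strand="-")]
        assert len(cluster_support(pairs, buffer=5)) == 2

    @pytest.mark.parametrize("seed", range(30))
    def test_sweep_equals_bruteforce(self, seed):
        pairs = _random_pairs(seed, n=120)
        fast = cluster_support(pairs, buffer=5)
        slow = cluster_support_bruteforce(pairs, buffer=5)
        assert [(c.chrom, c.strand, c.left_end, c.right_start, len(c.members)) for c in fast] == [
            (c.chrom, c.strand, c.left_end, c.right_start, len(c.members)) for c in slow
        ]


def _random_pairs(seed, n=120):
    """Dense random pairs on two chromosomes so buffer windows overlap."""
    rng = np.random.Generator(np.random.PCG64(seed))
    pairs = []
    for i in range(n):
        chrom = "chr1" if rng.integers(0, 4) else "chr2"
        strand = "+" if rng.integers(0, 5) else "-"
        le = int(rng.integers(100, 160))
        rs = le + int(rng.integers(50, 90))
        pairs.append(_pair(f"r{i}", chrom=chrom, strand=strand, left=(le - 20, le), right=(rs, rs + 20)))
    return pairs


class TestRescue:
    def _candidate(self, left_end=100, right_start=200, n_members=1):
        members = [_pair(f"m{i}", left=(left_end - 20, left_end), right=(right_start, right_start + 20))
                   for i in range(n_members)]
        return JunctionCandidate("chr1", "+", left_end, right_start, members)

    def _rescue_hit(self, read_id="x", side="L", end=102, chrom="chr1", strand="+"):
        return RescueHit(read_id, side, AlignmentHit(read_id, chrom, strand, end - 35, end))

    def test_left_side_within_buffer_rescues(self):
        cand = self._candidate()
        rescue_long_sides([self._rescue_hit(end=102)], [cand], buffer=5)
        assert cand.rescue_support == 1 and cand.support == 2

    def test_outside_buffer_no_rescue(self):
        cand = self._candidate()
        rescue_long_sides([self._rescue_hit(end=110)], [cand], buffer=5)
        assert cand.rescue_support == 0

    def test_right_side_uses_hit_start(self):
        cand = self._candidate()
        rh = RescueHit("x", "R", AlignmentHit("x", "chr1", "+", 203, 238))
        rescue_long_sides([rh], [cand], buffer=5)
        assert cand.rescue_support == 1

    def test_each_read_rescues_at_most_one_candidate(self):
        near, far = self._candidate(100, 200), self._candidate(104, 204)
        rescue_long_sides([self._rescue_hit(end=101)], [near, far], buffer=5)
        assert near.rescue_support == 1 and far.rescue_support == 0

    def test_member_read_never_rescued(self):
        cand = self._candidate()
        rescue_long_sides([self._rescue_hit(read_id="m0", end=100)], [cand], buffer=5)
        assert cand.rescue_support == 0

    def test_minus_strand_left_side_is_genomic_right(self):
        cand = JunctionCandidate("chr1", "-", 100, 200, [_pair("m", strand="-", left=(80, 100), right=(200, 220))])
        # read-left part on '-' strand sits at the genomic right boundary
        rh = RescueHit("x", "L", AlignmentHit("x", "chr1", "-", 201, 236))
        rescue_long_sides([rh], [cand], buffer=5)
        assert cand.rescue_support == 1


class TestCallJunctions:
    GENOME = [GenomeSequence("chr1", "A" * 100 + "CGTT" + "A" * 400)]

    def _cands(self, n_members, rescue=0):
        c = JunctionCandidate(
            "chr1", "+", 100, 200,
            [_pair(f"r{i}", left=(80, 100), right=(200, 220)) for i in range(n_members)],
            rescue_support=rescue,
        )
        return [c]

    def test_two_members_called_at_supp_two(self):
        calls = call_junctions(self._cands(2), self.GENOME, supp=2)
        assert len(calls) == 1
        assert calls[0].splice_length == 100
        assert calls[0].excised_sequence == self.GENOME[0].bases[100:200]

    def test_one_member_plus_one_rescue_called(self):
        assert len(call_junctions(self._cands(1, rescue=1), self.GENOME, supp=2)) == 1

    def test_one_member_alone_not_called(self):
        assert call_junctions(self._cands(1), self.GENOME, supp=2) == []

    def test_support_counts_distinct_reads(self):
        # one read split at two positions contributes two pairs but support 1
        c = JunctionCandidate(
            "chr1", "+", 100, 200,
            [_pair("same", p=20, left=(80, 100), right=(200, 220)),
             _pair("same", p=25, left=(75, 100), right=(200, 225))],
        )
        assert call_junctions([c], self.GENOME, supp=2) == []

    def test_supp_monotonicity(self):
        for n in range(1, 5):
            lo = call_junctions(self._cands(n), self.GENOME, supp=2)
            hi = call_junctions(self._cands(n), self.GENOME, supp=3)
            assert {c.key for c in hi} <= {c.key for c in lo}

    def test_known_novel_against_annotation(self):
        genes = [GeneModel("G", "T", "chr1", "+", 50, 300, (50, 200), (100, 300))]
        (call,) = call_junctions(self._cands(2), self.GENOME, supp=2, annotation=genes)
        assert call.novelty == "known"
        genes_off = [GeneModel("G", "T", "chr1", "+", 50, 300, (50, 201), (101, 300))]
        (call,) = call_junctions(self._cands(2), self.GENOME, supp=2, annotation=genes_off)
        assert call.novelty == "novel"


def _call(chrom="chr1", left=100, right=200):
    from splicescout.junctions import JunctionCall

    return JunctionCall(chrom, "+", left, right, right - left, 3, "G", "", "novel")


class TestCompareRuns:
    def test_identical_sets_all_common(self):
        a = [_call(), _call(left=500, right=700)]
        out = compare_runs(a, list(a), buffer=5)
        assert len(out["common"]) == 2 and not out["unique_a"] and not out["unique_b"]

    def test_disjoint_chromosomes(self):
        out = compare_runs([_call(chrom="chr1")], [_call(chrom="chr2")], buffer=5)
        assert not out["common"]
        assert len(out["unique_a"]) == 1 and len(out["unique_b"]) == 1

    def test_offset_exactly_buffer_is_common(self):
        out = compare_runs([_call()], [_call(left=105, right=205)], buffer=5)
        assert len(out["common"]) == 1

    def test_partition_exhaustive_and_disjoint(self):
        a = [_call(left=100 + 3 * i, right=300 + 3 * i) for i in range(10)]
        b = [_call(left=101 + 4 * i, right=301 + 4 * i) for i in range(8)]
        out = compare_runs(a, b, buffer=5)
        assert len(out["common"]) + len(out["unique_a"]) == len(a)
        assert len(out["common"]) + len(out["unique_b"]) == len(b)


def test_gene_index_overlap_resolution():
    genes = [
        _gene("OUTER", start=0, end=5000),
        _gene("INNER", start=100, end=900),
        _gene("ALSO", start=100, end=900),
    ]
    gi = GeneIndex(genes)
    assert gi.assign("chr1", 150, 800) == "ALSO"  # tie on span -> lexicographic
    assert gi.assign("chr1", 50, 800) == "OUTER"
    assert gi.assign("chr1", 4000, 6000) is None
    assert gi.assign("chrX", 0, 10) is None
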