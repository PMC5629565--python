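"""EST validation, known/novel classification, specificity/sensitivity,
RPKM binning, and the two-group frequency screen."""

import pytest

from splicescout.evaluate import (
    classify_known_novel,
    compute_rpkm,
    compute_rpkm_table,
    group_frequency_comparison,
    rpkm_bin,
    sensitivity,
    specificity,
    validate_with_est,
)
from splicescout.junctions import JunctionCall
from splicescout.seqio import EstInterval, GeneModel


def _call(chrom="chr1", left=100, right=200, novelty="novel", gene="G"):
    return JunctionCall(chrom, "+", left, right, right - left, 3, gene, "", novelty)


def _est(chrom="chr1", start=0, end=100):
    return EstInterval(chrom, start, end)


class TestEstValidation:
    def test_both_boundaries_within_buffer(self):
        ests = [_est(end=104), _est(start=196, end=400)]
        assert validate_with_est(_call(), ests, buffer=5)

    def test_left_end_offset_six_fails(self):
        ests = [_est(end=106), _est(start=196, end=400)]
        assert not validate_with_est(_call(), ests, buffer=5)

    def test_exact_buffer_offset_validates(self):
        ests = [_est(end=105), _est(start=195, end=400)]
        assert validate_with_est(_call(), ests, buffer=5)
        assert not validate_with_est(_call(), [_est(end=106), _est(start=194, end=400)], buffer=5)

    def test_no_ests_on_chromosome(self):
        assert not validate_with_est(_call(chrom="chr9"), [_est(end=100), _est(start=200, end=300)])

    def test_one_est_may_satisfy_both_sides(self):
        # a single EST ending at the left boundary and another starting at the
        # right; the two existential tests are independent
        assert validate_with_est(_call(), [_est(end=100), _est(start=200, end=300)], buffer=0)

    @pytest.mark.parametrize("b1,b2", [(0, 3), (3, 10), (5, 50)])
    def test_monotone_in_buffer(self, b1, b2):
        ests = [_est(end=103), _est(start=198, end=400)]
        if validate_with_est(_call(), ests, buffer=b1):
            assert validate_with_est(_call(), ests, buffer=b2)


class TestKnownNovel:
    GENES = [GeneModel("G", "T", "chr1", "+", 0, 1000, (0, 200, 600), (100, 400, 1000))]

    def test_exact_intron_is_known(self):
        assert classify_known_novel(_call(left=100, right=200), self.GENES) == "known"
        assert classify_known_novel(_call(left=400, right=600), self.GENES) == "known"

    def test_inside_exon_is_novel(self):
        assert classify_known_novel(_call(left=210, right=280), self.GENES) == "novel"

    def test_tolerance(self):
        off = _call(left=101, right=201)
        assert classify_known_novel(off, self.GENES, tolerance=0) == "novel"
        assert classify_known_novel(off, self.GENES, tolerance=5) == "known"


class TestSpecificity:
    def test_fraction_validated(self):
        calls = [_call(left=100 * i, right=100 * i + 50) for i in range(1, 11)]
        ests = []
        for c in calls[:8]:
            ests += [_est(end=c.left_end), _est(start=c.right_start, end=c.right_start + 10)]
        out = specificity(calls, ests, buffer=5)
        assert out["all"] == pytest.approx(0.8)

    def test_novel_ratio(self):
        calls = [_call(left=100, right=150, novelty="novel"),
                 _call(left=300, right=350, novelty="novel"),
                 _call(left=500, right=550, novelty="novel"),
                 _call(left=700, right=750, novelty="novel")]
        ests = []
        for c in calls[:3]:
            ests += [_est(end=c.left_end), _est(start=c.right_start, end=c.right_start + 10)]
        assert specificity(calls, ests)["novel"] == pytest.approx(0.75)

    def test_zero_novel_reported_absent(self):
        out = specificity([_call(novelty="known")], [])
        assert out["novel"] is None
        assert out["all"] == 0.0


class TestSensitivity:
    GENE = [GeneModel("G", "T", "chr1", "+", 0, 1000, (0, 200, 600), (100, 400, 1000))]

    def test_both_introns_detected(self):
        calls = [_call(left=100, right=200, novelty="known"), _call(left=400, right=600, novelty="known")]
        assert sensitivity(calls, self.GENE)["overall"] == pytest.approx(1.0)

    def test_one_of_two_introns(self):
        calls = [_call(left=100, right=200, novelty="known")]
        out = sensitivity(calls, self.GENE)
        assert out["overall"] == pytest.approx(0.5)
        assert (out["n_detected"], out["n_possible"]) == (1, 2)

    def test_undetected_gene_excluded_from_denominator(self):
        other = GeneModel("H", "T2", "chr1", "+", 2000, 3000, (2000, 2500), (2200, 3000))
        calls = [_call(left=100, right=200, novelty="known")]
        out = sensitivity(calls, self.GENE + [other])
        assert out["overall"] == pytest.approx(0.5)  # H contributes nothing

    def test_single_isoform_restriction(self):
        iso2 = GeneModel("G", "T2", "chr1", "+", 0, 1000, (0, 600), (100, 1000))
        calls = [_call(left=100, right=200, novelty="known")]
        both = sensitivity(calls, self.GENE + [iso2])
        single = sensitivity(calls, self.GENE + [iso2], single_isoform_only=True)
        assert both["overall"] is not None and single["overall"] is None
        # multi-isoform gene: junction union across isoforms is the denominator
        assert both["n_possible"] == 3

    def test_per_bin_reporting(self):
        calls = [_call(left=100, right=200, novelty="known")]
        mapped = [("chr1", 10)] * 100
        rec = compute_rpkm(self.GENE, mapped, total_mapped=10_000)
        out = sensitivity(calls, self.GENE, rpkm=[rec])
        assert out["bins"][rec.bin]["overall"] == pytest.approx(0.5)
        assert sum(1 for b in out["bins"].values() if b["n_possible"]) == 1


class TestRpkm:
    def test_formula_and_bin(self):
        gene = [GeneModel("G", "T", "chr1", "+", 0, 3000, (0, 1500), (1000, 2500))]
        mapped = [("chr1", 5)] * 60 + [("chr1", 1600)] * 40 + [("chr2", 5)] * 7
        rec = compute_rpkm(gene, mapped, total_mapped=10_000_000)
        assert rec.exonic_length == 2000
        assert rec.read_count == 100
        assert rec.rpkm == pytest.approx(5.0)
        assert rec.bin == 2

    def test_zero_reads_bin_one(self):
        gene = [GeneModel("G", "T", "chr1", "+", 0, 100, (0,), (100,))]
        rec = compute_rpkm(gene, [], total_mapped=1000)
        assert rec.rpkm == 0.0 and rec.bin == 1

    @pytest.mark.parametrize(
        "value,expected", [(0.0, 1), (4.999, 1), (5.0, 2), (9.99, 2), (10.0, 3), (49.9, 3), (50.0, 4), (99.9, 4), (100.0, 5), (1e6, 5)]
    )
    def test_bin_boundaries(self, value, expected):
        assert rpkm_bin(value) == expected

    def test_total_mapped_zero_rejected(self):
        gene = [GeneModel("G", "T", "chr1", "+", 0, 100, (0,), (100,))]
        with pytest.raises(ValueError):
            compute_rpkm(gene, [], total_mapped=0)

    def test_bin_partition_sums_to_gene_count(self):
        genes = [
            GeneModel(f"G{i}", f"T{i}", "chr1", "+", 1000 * i, 1000 * i + 500, (1000 * i,), (1000 * i + 500,))
            for i in range(6)
        ]
        mapped = [("chr1", 1000 * i + 5) for i in range(6) for _ in range(4 ** i)]
        table = compute_rpkm_table(genes, mapped, total_mapped=100_000)
        assert len(table) == 6
        from collections import Counter

        assert sum(Counter(r.bin for r in table).values()) == 6


class TestGroupFrequency:
    def _samples(self, present_a, present_b, size_a=4, size_b=4):
        calls = {f"a{i}": [_call()] if i < present_a else [] for i in range(size_a)}
        calls |= {f"b{i}": [_call()] if i < present_b else [] for i in range(size_b)}
        labels = {f"a{i}": "a" for i in range(size_a)} | {f"b{i}": "b" for i in range(size_b)}
        return calls, labels

    def test_delta_half_excluded_at_strict_threshold(self):
        calls, labels = self._samples(3, 1)
        assert group_frequency_comparison(calls, labels, threshold=0.5) == []

    def test_full_contrast_included(self):
        calls, labels = self._samples(4, 0)
        (row,) = group_frequency_comparison(calls, labels, threshold=0.5)
        assert row.delta == pytest.approx(1.0)

    def test_absent_junction_not_a_row(self):
        calls, labels = self._samples(0, 0)
        assert group_frequency_comparison(calls, labels) == []

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_frequency_comparison({"s": []}, {"s": "a"})

    def test_b_enriched_negative_delta(self):
        calls, labels = self._samples(0, 4)
        (row,) = group_frequency_comparison(calls, labels)
        assert row.delta == pytest.approx(-1.0)
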