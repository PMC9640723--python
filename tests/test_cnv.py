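from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lohscape import cnv
from lohscape.model import CNCategory, GeneModel

import naive_scoring
from conftest import make_profile


class TestBinning:
    @pytest.mark.parametrize("cn, expected", [
        (0, CNCategory.DELETION), (1, CNCategory.LOSS),
        (2, CNCategory.NEUTRAL), (3, CNCategory.NEUTRAL),
        (4, CNCategory.GAIN), (5, CNCategory.GAIN),
        (6, CNCategory.AMPLIFICATION), (7, CNCategory.AMPLIFICATION),
        (25, CNCategory.AMPLIFICATION),
    ])
    def test_table_mapping(self, cn, expected):
        assert cnv.bin_copy_number(cn) is expected

    def test_surjective_over_small_inputs(self):
        assert {cnv.bin_copy_number(i) for i in range(7)} == set(CNCategory)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            cnv.bin_copy_number(-1)


class TestGeneAnnotation:
    def test_gene_inside_single_gain_segment(self):
        profile = make_profile([("chr1", 1, 1000, 3, 1)])
        call = cnv.annotate_gene_cn(GeneModel("G", "chr1", 100, 200), profile)
        assert (call.min_cn, call.category) == (4, CNCategory.GAIN)
        assert not call.qualifies_amplified
        assert call.covered_fraction == 1.0

    def test_partial_amplification_fails_100_percent_rule(self):
        # 60% at CN 6, 40% at CN 2
        profile = make_profile([("chr1", 1, 160, 5, 1), ("chr1", 161, 1000, 1, 1)])
        call = cnv.annotate_gene_cn(GeneModel("G", "chr1", 101, 200), profile)
        assert call.min_cn == 2
        assert not call.qualifies_amplified

    def test_full_amplification_coverage_qualifies(self):
        profile = make_profile([("chr1", 1, 1000, 5, 1)])
        call = cnv.annotate_gene_cn(GeneModel("G", "chr1", 100, 200), profile)
        assert call.qualifies_amplified

    def test_majority_deletion_qualifies_deleted(self):
        # 70% of the gene inside a CN 0 segment
        profile = make_profile([("chr1", 1, 170, 0, 0), ("chr1", 171, 1000, 1, 1)])
        call = cnv.annotate_gene_cn(GeneModel("G", "chr1", 101, 200), profile)
        assert call.qualifies_deleted

    def test_uncovered_gene_portions_count_toward_no_category(self):
        # deletion covers 40% of the gene, the rest uncovered
        profile = make_profile([("chr1", 101, 140, 0, 0)])
        call = cnv.annotate_gene_cn(GeneModel("G", "chr1", 101, 200), profile)
        assert not call.qualifies_deleted
        assert call.covered_fraction == pytest.approx(0.4)

    def test_absent_chromosome_gives_no_call(self):
        profile = make_profile([("chr1", 1, 1000, 1, 1)])
        call = cnv.annotate_gene_cn(GeneModel("G", "chr9", 1, 100), profile)
        assert call.min_cn is None and call.category is None

    def test_invariant_under_same_cn_splitting(self):
        whole = make_profile([("chr1", 1, 1000, 3, 1)])
        split = make_profile([("chr1", 1, 150, 3, 1), ("chr1", 151, 1000, 3, 1)])
        gene = GeneModel("G", "chr1", 100, 200)
        a, b = cnv.annotate_gene_cn(gene, whole), cnv.annotate_gene_cn(gene, split)
        assert (a.min_cn, a.category, a.covered_fraction_by_category) == \
            (b.min_cn, b.category, b.covered_fraction_by_category)


class TestSetComparison:
    def test_reciprocal_overlap_arithmetic(self):
        a, b = ("chr1", 1, 100), ("chr1", 41, 140)
        assert cnv.reciprocal_overlap(a, b, 0.5)       # 60 bp = 60% of each
        assert not cnv.reciprocal_overlap(a, b, 0.7)

    def test_identical_sets_all_shared(self):
        s = [("chr1", 1, 100), ("chr2", 50, 500)]
        cmp = cnv.compare_segment_sets(s, list(s))
        assert cmp.private_a == [] and cmp.private_b == []
        assert cmp.jaccard == 1.0

    def test_disjoint_sets_all_private(self):
        cmp = cnv.compare_segment_sets([("chr1", 1, 100)], [("chr1", 200, 300)])
        assert cmp.shared_a == [] and cmp.shared_b == []
        assert cmp.jaccard == 0.0

    def test_partition_of_inputs(self):
        a = [("chr1", 1, 100), ("chr1", 300, 400), ("chr2", 1, 50)]
        b = [("chr1", 41, 140), ("chr2", 500, 600)]
        cmp = cnv.compare_segment_sets(a, b)
        assert sorted(cmp.shared_a + cmp.private_a) == sorted(a)
        assert sorted(cmp.shared_b + cmp.private_b) == sorted(b)

    def test_jaccard_symmetric_and_matches_per_basepair(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            def rand_set():
                return [("chr1", int(s), int(s + rng.integers(1, 50)))
                        for s in rng.integers(1, 500, size=rng.integers(1, 6))]
            a, b = rand_set(), rand_set()
            j_ab, j_ba = cnv.jaccard(a, b), cnv.jaccard(b, a)
            assert j_ab == pytest.approx(j_ba)
            assert j_ab == pytest.approx(naive_scoring.naive_jaccard(a, b))


class TestMinimalCommonRegion:
    def test_three_identical_intervals(self):
        iv = ("chr1", 10, 50)
        region, support = cnv.minimal_common_region([[iv], [iv], [iv]])
        assert (region, support) == (iv, 3)

    def test_nested_overlap_example(self):
        lists = [[("chr1", 1, 100)], [("chr1", 50, 200)], [("chr1", 60, 80)]]
        region, support = cnv.minimal_common_region(lists)
        assert (region, support) == (("chr1", 60, 80), 3)

    def test_disjoint_below_support_is_empty(self):
        region, support = cnv.minimal_common_region(
            [[("chr1", 1, 10)], [("chr1", 100, 110)]], min_support=2)
        assert region is None and support == 0

    def test_matches_per_basepair_support_on_random_instances(self):
        rng = np.random.default_rng(13)
        for _ in range(100):
            lists = []
            for _ in range(rng.integers(1, 5)):
                lists.append([("chr1", int(s), int(s + rng.integers(1, 40)))
                              for s in rng.integers(1, 300, size=rng.integers(1, 4))])
            got = cnv.minimal_common_region(lists)
            want = naive_scoring.naive_mcr(lists)
            assert got == want


class TestGeneRanking:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["gene", "patient_id", "group", "category"])

    def test_patient_counted_once_per_group(self):
        rows = [("PARP1", "P1", "recurrent", "Amplification")] * 3
        ranked = cnv.rank_genes_by_cn_event(self._calls(rows), "gain_or_amp", "recurrent")
        assert ranked == [("PARP1", 1)]

    def test_empty_cohort_empty_ranking(self):
        ranked = cnv.rank_genes_by_cn_event(self._calls([]), "gain_or_amp", "primary")
        assert ranked == []

    def test_ties_broken_lexicographically(self):
        rows = [("ZZZ", "P1", "primary", "Gain"), ("ZZZ", "P2", "primary", "Gain"),
                ("AAA", "P1", "primary", "Amplification"), ("AAA", "P2", "primary", "Gain")]
        ranked = cnv.rank_genes_by_cn_event(self._calls(rows), "gain_or_amp", "primary")
        assert ranked == [("AAA", 2), ("ZZZ", 2)]

    def test_unknown_group_raises(self):
        rows = [("G", "P1", "primary", "Gain")]
        with pytest.raises(ValueError, match="unknown group"):
            cnv.rank_genes_by_cn_event(self._calls(rows), "gain_or_amp", "metastasis")

    def test_unknown_event_raises(self):
        with pytest.raises(ValueError, match="unknown event"):
            cnv.rank_genes_by_cn_event(self._calls([]), "whatever", "primary")
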