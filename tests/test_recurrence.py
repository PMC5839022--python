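"""Cross-family recurrence categories and the rare single-trio filter."""

import random

from trioseg.recurrence import cross_trio_recurrence, single_trio_rare_recessive
from trioseg.segregation import SegregationCall, CompHetPair, find_compound_hets, segregate_all
from trioseg.variants import VariantScores

from conftest import load_fixture_records


def call(trio, gene, seg_class, chrom="chr1", pos=100, alt="G"):
    return SegregationCall(
        trio_id=trio, key=f"{chrom}:{pos}:A:{alt}", chrom=chrom, pos=pos,
        ref="A", alt=alt, gene=gene, consequence="missense",
        seg_class=seg_class,
    )


class TestCategories:
    def test_identical_variant_in_two_trios_is_category_a(self):
        calls = [call("T1", "Sec16A", "recessive_hom", "chr9", 139368953),
                 call("T2", "Sec16A", "recessive_hom", "chr9", 139368953)]
        report = cross_trio_recurrence(calls)
        assert [v.gene for v in report.category_a] == ["Sec16A"]
        assert report.category_b == []
        assert report.totals["A_variants"] == 1

    def test_distinct_positions_in_shared_gene_is_category_b(self):
        calls = [call("T1", "KNL1", "recessive_hom", "chr15", 40916237),
                 call("T2", "KNL1", "recessive_hom", "chr15", 40915190),
                 call("T3", "KNL1", "recessive_hom", "chr15", 40914177)]
        report = cross_trio_recurrence(calls)
        assert [g.gene for g in report.category_b] == ["KNL1"]
        assert report.totals["B_variants"] == 3

    def test_comp_het_gene_in_two_trios_is_category_c(self):
        pairs = [
            CompHetPair("T2", "DNAH11", ("chr7:21893993:A:G",),
                        ("chr7:21584693:A:G",)),
            CompHetPair("T3", "DNAH11", ("chr7:21628242:A:G",),
                        ("chr7:21678643:A:G",)),
        ]
        report = cross_trio_recurrence(
            [call("T2", "X", "inherited_other"), call("T3", "Y", "inherited_other")],
            pairs,
        )
        assert [g.gene for g in report.category_c] == ["DNAH11"]
        assert report.totals["C_variants"] == 4

    def test_single_trio_gene_absent_from_all_categories(self):
        calls = [call("T1", "NDUFV3", "recessive_hom", "chr21", 44317156),
                 call("T2", "OTHER", "inherited_other", "chr2", 5)]
        report = cross_trio_recurrence(calls)
        assert report.totals["total_variants"] == 0

    def test_gene_in_a_excluded_from_b(self):
        calls = [
            call("T1", "G1", "recessive_hom", "chr1", 100),
            call("T2", "G1", "recessive_hom", "chr1", 100),  # same variant -> A
            call("T3", "G1", "recessive_hom", "chr1", 200),  # extra position
        ]
        report = cross_trio_recurrence(calls)
        assert [v.gene for v in report.category_a] == ["G1"]
        assert report.category_b == []

    def test_fewer_than_two_trios_empty_report(self):
        report = cross_trio_recurrence([call("T1", "G1", "recessive_hom")])
        assert report.totals["total_variants"] == 0


class TestFixtureRecurrence:
    def test_printed_totals(self, fixture_paths, trios, manifest):
        recs = load_fixture_records(fixture_paths["recurrence"], trios)
        calls, _ = segregate_all(recs, trios)
        report = cross_trio_recurrence(calls, find_compound_hets(calls))
        expected = manifest["recurrence"]
        assert report.totals["A_variants"] == expected["A_variants"]
        assert report.totals["B_genes"] == expected["B_genes"]
        assert report.totals["B_variants"] == expected["B_variants"]
        assert report.totals["C_genes"] == expected["C_genes"]
        assert report.totals["C_variants"] == expected["C_variants"]
        assert report.totals["total_variants"] == expected["total_variants"]

    def test_a_and_b_gene_sets_disjoint_but_c_may_overlap_b(
        self, fixture_paths, trios
    ):
        recs = load_fixture_records(fixture_paths["recurrence"], trios)
        calls, _ = segregate_all(recs, trios)
        report = cross_trio_recurrence(calls, find_compound_hets(calls))
        a = {v.gene for v in report.category_a}
        b = {g.gene for g in report.category_b}
        c = {g.gene for g in report.category_c}
        assert not (a & b)
        assert "DNAH11" in (b & c)  # same gene, different variant sets

    def test_invariant_to_trio_input_order(self, fixture_paths, trios):
        recs = load_fixture_records(fixture_paths["recurrence"], trios)
        calls, _ = segregate_all(recs, trios)
        pairs = find_compound_hets(calls)
        base = cross_trio_recurrence(calls, pairs).totals
        rng = random.Random(3)
        for _ in range(3):
            shuffled = calls[:]
            rng.shuffle(shuffled)
            assert cross_trio_recurrence(shuffled, pairs).totals == base


class TestRareSingleTrio:
    def test_rare_retained_common_excluded_missing_rare(self):
        calls = [
            call("T1", "NDUFV3", "recessive_hom", "chr21", 44317156),
            call("T1", "Sec16A", "recessive_hom", "chr9", 139368953),
            call("T1", "COG6", "recessive_hom", "chr13", 40254100),
        ]
        scores = {
            calls[0].key: VariantScores(maf=0.0051),
            calls[1].key: VariantScores(maf=0.21),
            calls[2].key: VariantScores(maf=None),
        }
        kept = single_trio_rare_recessive(calls, scores, maf_threshold=0.01)
        assert sorted(c.gene for c in kept) == ["COG6", "NDUFV3"]
        strict = single_trio_rare_recessive(calls, scores, maf_threshold=0.01,
                                            missing_is_rare=False)
        assert [c.gene for c in strict] == ["NDUFV3"]

    def test_multi_trio_variant_excluded_even_if_rare(self):
        calls = [call("T1", "G", "recessive_hom", "chr1", 5),
                 call("T2", "G", "recessive_hom", "chr1", 5)]
        assert single_trio_rare_recessive(calls, {}) == []

    def test_fixture_retains_exactly_nine(self, fixture_paths, trios, manifest):
        recs = load_fixture_records(fixture_paths["rare_recessive"], trios)
        calls, _ = segregate_all(recs, trios)
        kept = single_trio_rare_recessive(
            calls, {r.key: r.scores for r in recs}, maf_threshold=0.01
        )
        assert len(kept) == manifest["rare_recessive"]["retained_at_maf_0.01"]
        assert sorted({c.gene for c in kept}) == [
            "BEGAIN", "CHRNA3", "COG6", "DCP1B", "FMNL1", "NDUFV3",
            "SHROOM1", "WNT2", "ZNF717",
        ]
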