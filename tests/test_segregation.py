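"""Inheritance classification, compound hets and the segregation driver."""

import itertools

import pytest

from trioseg.filters import transmission_table
from trioseg.segregation import (
    SEG_CLASSES,
    classify_trio_genotype,
    find_compound_hets,
    mendelian_consistent,
    segregate_all,
)
from trioseg.simulate import SimConfig, simulate_trio_dataset
from trioseg import io as tio

from conftest import load_fixture_records


class TestClassify:
    @pytest.mark.parametrize(
        "triple,expected",
        [
            ((1, 0, 0), "de_novo"),
            ((2, 1, 1), "recessive_hom"),
            ((2, 0, 1), "mendelian_error"),
            ((1, 1, 0), "het_paternal"),
            ((1, 0, 1), "het_maternal"),
            ((1, 1, 1), "het_biparental"),
            ((1, 2, 1), "het_biparental"),
            ((2, 2, 1), "inherited_other"),
            ((2, 2, 2), "inherited_other"),
            ((0, 0, 0), "inherited_other"),
            ((0, 2, 0), "mendelian_error"),
            ((1, 2, 2), "mendelian_error"),
            ((None, 0, 0), "uncalled"),
            ((1, None, 0), "uncalled"),
        ],
    )
    def test_examples(self, triple, expected):
        assert classify_trio_genotype(*triple) == expected

    def test_partition_over_all_triples(self):
        """Every called triple maps to exactly one class of the vocabulary."""
        for c, f, m in itertools.product(range(3), repeat=3):
            cls = classify_trio_genotype(c, f, m)
            assert cls in SEG_CLASSES and cls != "uncalled"

    def test_parent_swap_symmetry(self):
        swap = {"het_paternal": "het_maternal", "het_maternal": "het_paternal"}
        for c, f, m in itertools.product(range(3), repeat=3):
            a = classify_trio_genotype(c, f, m)
            b = classify_trio_genotype(c, m, f)
            assert b == swap.get(a, a)

    def test_mendelian_error_is_complement_of_mu0_transmission(self):
        """mendelian_error (plus the de novo configuration) is exactly the
        set of triples with zero mass in the mu=0 transmission table."""
        T = transmission_table(0.0)
        for c, f, m in itertools.product(range(3), repeat=3):
            impossible = T[f, m, c] == 0.0
            cls = classify_trio_genotype(c, f, m)
            if cls == "mendelian_error":
                assert impossible
            elif cls == "de_novo":
                assert impossible  # the one violation called out by name
            else:
                assert not impossible
            assert mendelian_consistent(c, f, m) == (not impossible)


def _call(trio, gene, seg_class, pos):
    from trioseg.segregation import SegregationCall

    return SegregationCall(
        trio_id=trio, key=f"chr1:{pos}:A:G", chrom="chr1", pos=pos,
        ref="A", alt="G", gene=gene, consequence="missense",
        seg_class=seg_class,
    )


class TestCompoundHets:
    def test_one_pair_per_gene_and_trio(self):
        calls = [
            _call("T1", "IDO2", "het_paternal", 39862881),
            _call("T1", "IDO2", "het_maternal", 39873053),
            _call("T1", "RREB1", "het_paternal", 7231843),
            _call("T1", "RREB1", "het_maternal", 7246998),
        ]
        pairs = find_compound_hets(calls)
        assert [(p.trio_id, p.gene_symbol) for p in pairs] == [
            ("T1", "IDO2"), ("T1", "RREB1")
        ]
        assert pairs[0].paternal_variants == ("chr1:39862881:A:G",)
        assert pairs[0].maternal_variants == ("chr1:39873053:A:G",)

    def test_same_side_only_never_pairs(self):
        calls = [
            _call("T1", "G1", "het_paternal", 10),
            _call("T1", "G1", "het_paternal", 20),
        ]
        assert find_compound_hets(calls) == []

    def test_biparental_hets_excluded(self):
        calls = [
            _call("T1", "G1", "het_biparental", 10),
            _call("T1", "G1", "het_maternal", 20),
        ]
        assert find_compound_hets(calls) == []


class TestSegregateAll:
    def test_denovo_fixture_counts(self, fixture_paths, trios):
        recs = load_fixture_records(fixture_paths["denovo"], trios)
        calls, summary = segregate_all(recs, trios)
        assert summary.total("de_novo") == 6
        assert [summary.class_counts[t]["de_novo"] for t in ("T1", "T2", "T3")] \
            == [2, 2, 2]
        genes = sorted(c.gene for c in calls if c.seg_class == "de_novo")
        assert genes == ["CTNND2", "IGSF3", "NPHS2", "PRSS55", "SPICE1",
                         "ZNF717"]

    def test_all_reference_trio_yields_no_events(self, tmp_path):
        ds = simulate_trio_dataset(
            SimConfig(n_trios=1, n_variants=0, n_denovo=0, seed=1), tmp_path
        )
        trios = tio.read_pedigree(ds.ped)
        calls, summary = segregate_all(
            list(tio.read_trio_vcf(ds.vcf, trios)), trios
        )
        for cls in ("de_novo", "recessive_hom", "mendelian_error"):
            assert summary.total(cls) == 0

    def test_noise_free_simulation_matches_truth_exactly(self, tmp_path):
        config = SimConfig(
            n_trios=2, n_variants=300, n_denovo=2,
            recessive_genes={"T1": ["RECA"], "T2": ["RECB", "RECC"]},
            comphet_genes={"T1": ["CHA"]},
            allele_depth_noise=False, seed=7,
        )
        ds = simulate_trio_dataset(config, tmp_path)
        trios = tio.read_pedigree(ds.ped)
        recs = list(tio.read_trio_vcf(
            ds.vcf, trios, score_table=tio.read_score_table(ds.scores)
        ))
        calls, _ = segregate_all(recs, trios)
        for cls in ("de_novo", "recessive_hom"):
            pred = {(c.trio_id, c.key) for c in calls if c.seg_class == cls}
            assert pred == ds.truth.of_class(cls)
        pairs = find_compound_hets(calls)
        members = {(p.trio_id, k) for p in pairs for k in p.variant_keys}
        assert members == ds.truth.of_class("comp_het_member")

    def test_denovo_parent_read_level_flag(self, tmp_path):
        """Optional stricter rule: alternate reads in a parent veto de novo."""
        from trioseg.variants import (PedigreeTrio, SampleGenotype,
                                      TrioVariantRecord)

        trio = PedigreeTrio("F1", "c", "p", "m")
        rec = TrioVariantRecord(
            chrom="chr1", pos=10, ref="A", alt="G", qual=50,
            genotypes={
                "c": SampleGenotype((0, 1), 10, 10, 20, 99, (99, 0, 99)),
                "p": SampleGenotype((0, 0), 18, 2, 20, 60, (0, 60, 600)),
                "m": SampleGenotype((0, 0), 20, 0, 20, 60, (0, 60, 600)),
            },
        )
        strict, _ = segregate_all([rec], [trio],
                                  denovo_requires_parent_ref_reads=True)
        lax, _ = segregate_all([rec], [trio])
        assert lax[0].seg_class == "de_novo"
        assert strict[0].seg_class == "inherited_other"
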