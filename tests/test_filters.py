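"""Hard genotype filters and the pedigree-informed genotype posterior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trioseg.filters import (
    DeNovoPrior,
    FilterThresholds,
    allele_balance,
    genotype_posterior_from_pls,
    passes_genotype_filters,
    trio_genotype_posterior,
)
from trioseg.segregation import mendelian_consistent
from trioseg.variants import PedigreeTrio, SampleGenotype, TrioVariantRecord

TRIO = PedigreeTrio("F1", "c", "p", "m")


def gt(alleles, ad=(10, 10), gq=99, pl=None, depth=None):
    d = depth if depth is not None else sum(ad)
    return SampleGenotype(alleles=alleles, ad_ref=ad[0], ad_alt=ad[1],
                          depth=d, gq=gq, pl=pl)


def record(child, father, mother, maf=None):
    from trioseg.variants import VariantScores

    return TrioVariantRecord(
        chrom="chr1", pos=100, ref="A", alt="G", qual=50,
        genotypes={"c": child, "p": father, "m": mother},
        scores=VariantScores(maf=maf),
    )


class TestAlleleBalance:
    @pytest.mark.parametrize(
        "ad_ref,ad_alt,expected",
        [(10, 10, 0.5), (65, 35, 0.35), (90, 10, 0.10)],
    )
    def test_het_fraction(self, ad_ref, ad_alt, expected):
        assert allele_balance(gt((0, 1), (ad_ref, ad_alt))) == pytest.approx(expected)

    def test_homozygous_and_zero_depth_undefined(self):
        assert allele_balance(gt((1, 1), (0, 30))) is None
        assert allele_balance(gt((0, 1), (0, 0), depth=0)) is None


class TestHardFilters:
    def test_clean_trio_passes(self):
        rec = record(gt((0, 1), gq=21), gt((0, 0), (20, 0)), gt((0, 0), (20, 0)))
        assert passes_genotype_filters(rec, TRIO).record_pass

    def test_gq_strictly_greater_than_threshold(self):
        rec = record(gt((0, 1), gq=20), gt((0, 0), (20, 0)), gt((0, 0), (20, 0)))
        d = passes_genotype_filters(rec, TRIO)
        assert not d.member_pass["c"] and not d.record_pass

    @pytest.mark.parametrize("ad,ok", [((66, 34), False), ((65, 35), True),
                                       ((35, 65), True), ((34, 66), False)])
    def test_ab_bounds_inclusive(self, ad, ok):
        rec = record(gt((0, 1), ad), gt((0, 0), (20, 0)), gt((0, 0), (20, 0)))
        assert passes_genotype_filters(rec, TRIO).record_pass is ok

    def test_hom_alt_exempt_from_ab(self):
        rec = record(gt((1, 1), (1, 49)), gt((0, 1)), gt((0, 1)))
        assert passes_genotype_filters(rec, TRIO).record_pass

    def test_missing_gq_fails_conservatively(self):
        rec = record(gt((0, 1), gq=None), gt((0, 0), (20, 0)), gt((0, 0), (20, 0)))
        assert not passes_genotype_filters(rec, TRIO).record_pass

    def test_parent_ab_flag(self):
        rec = record(gt((0, 1)), gt((0, 1), (90, 10)), gt((0, 0), (20, 0)))
        assert not passes_genotype_filters(rec, TRIO).record_pass
        assert passes_genotype_filters(rec, TRIO, ab_on_parents=False).record_pass


def posterior_oracle(pl_c, pl_f, pl_m, mu, q):
    """Literal triple-loop enumeration of the 27 genotype triples."""
    def lik(pl):
        l = [10 ** (-x / 10) for x in pl]
        s = sum(l)
        return [x / s for x in l]

    Lc, Lf, Lm = lik(pl_c), lik(pl_f), lik(pl_m)
    H = [(1 - q) ** 2, 2 * q * (1 - q), q * q]
    p_alt = [mu, 0.5, 1 - mu]
    joint = np.zeros((3, 3, 3))
    for c in range(3):
        for f in range(3):
            for m in range(3):
                pf, pm = p_alt[f], p_alt[m]
                t = [(1 - pf) * (1 - pm),
                     pf * (1 - pm) + (1 - pf) * pm,
                     pf * pm][c]
                joint[c, f, m] = Lc[c] * Lf[f] * Lm[m] * t * H[f] * H[m]
    return joint / joint.sum()


pl_triples = st.tuples(*[st.integers(0, 120)] * 3)


class TestTrioPosterior:
    @given(pl_triples, pl_triples, pl_triples,
           st.sampled_from([0.0, 1e-6, 1e-4]),
           st.floats(0.001, 0.5))
    def test_matches_triple_loop_oracle_and_sums_to_one(
        self, pl_c, pl_f, pl_m, mu, q
    ):
        post = genotype_posterior_from_pls(pl_c, pl_f, pl_m, mu, q)
        assert post.joint.sum() == pytest.approx(1.0, abs=1e-9)
        oracle = posterior_oracle(pl_c, pl_f, pl_m, mu, q)
        np.testing.assert_allclose(post.joint, oracle, rtol=1e-12, atol=1e-300)

    def test_mu_zero_forbids_mendelian_violations(self):
        post = genotype_posterior_from_pls([0, 0, 0], [0, 0, 0], [0, 0, 0],
                                           mu=0.0, pop_alt_freq=0.3)
        for c in range(3):
            for f in range(3):
                for m in range(3):
                    if not mendelian_consistent(c, f, m):
                        assert post.joint[c, f, m] == 0.0
                    else:
                        assert post.joint[c, f, m] > 0.0

    def test_certain_homref_parents_flat_child(self):
        post = genotype_posterior_from_pls([0, 0, 0], [0, 255, 255],
                                           [0, 255, 255], mu=0.0,
                                           pop_alt_freq=0.01)
        np.testing.assert_allclose(post.child_marginal, [1, 0, 0], atol=1e-12)
        assert post.reassigned_child_gt == (0, 0)

    def test_flat_likelihoods_posterior_equals_prior(self):
        mu, q = 0.0, 0.2
        post = genotype_posterior_from_pls([0, 0, 0], [0, 0, 0], [0, 0, 0],
                                           mu=mu, pop_alt_freq=q)
        oracle = posterior_oracle([0, 0, 0], [0, 0, 0], [0, 0, 0], mu, q)
        np.testing.assert_allclose(post.joint, oracle, rtol=1e-12)

    def test_weak_denovo_evidence_is_suppressed(self):
        """Child PL [30,0,30] against certain hom-ref parents: the het
        posterior collapses to ~2e-6 / (2e-6 + 1e-3) ~= 0.002."""
        post = genotype_posterior_from_pls([30, 0, 30], [0, 255, 255],
                                           [0, 255, 255], mu=1e-6,
                                           pop_alt_freq=0.01)
        assert post.child_marginal[1] == pytest.approx(0.002, rel=0.05)
        assert post.reassigned_child_gt == (0, 0)

    @given(st.integers(0, 80), st.integers(0, 80))
    def test_weaker_het_evidence_never_raises_het_posterior(self, pl_het_1, d):
        pl_het_2 = pl_het_1 + d
        base = [30, 0, 30]
        p1 = genotype_posterior_from_pls([30, pl_het_1, 30], base, base,
                                         1e-6, 0.01).child_marginal[1]
        p2 = genotype_posterior_from_pls([30, pl_het_2, 30], base, base,
                                         1e-6, 0.01).child_marginal[1]
        assert p2 <= p1 + 1e-12

    def test_missing_pl_returns_none(self):
        rec = record(gt((0, 1), pl=None), gt((0, 0), pl=(0, 60, 600)),
                     gt((0, 0), pl=(0, 60, 600)))
        assert trio_genotype_posterior(rec, TRIO) is None

    def test_reassigned_gq_capped_at_99(self):
        post = genotype_posterior_from_pls([255, 0, 255], [0, 255, 255],
                                           [255, 0, 255], mu=1e-6,
                                           pop_alt_freq=0.01)
        assert post.reassigned_child_gq <= 99.0


class TestThresholdValidation:
    def test_bad_ab_window_rejected(self):
        with pytest.raises(ValueError):
            FilterThresholds(ab_min=0.6, ab_max=0.65)

    def test_mu_range(self):
        with pytest.raises(ValueError):
            DeNovoPrior(mu=0.01)
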